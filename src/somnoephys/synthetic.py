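"""Seeded synthetic sessions with known ground truth.

The generator plants every statistical feature the downstream estimators
measure: a semi-Markov Move/Rest/REM/NREM sequence on 8-s bins with
nocturnal NREM-REM cycling and daytime naps; per-state LFP band power on a
1/f^alpha background; a shared cross-channel component controlling
coherence; low-band-phase -> high-band-amplitude coupling with configurable
depth and preferred phase; state-dependent head-acceleration variance with
movement bursts; and spike trains with state-dependent rates, refractory
ISI structure and von Mises phase locking to chosen bands.

Sub-50 Hz oscillations are sums of amplitude-stabilized stochastic-
frequency oscillators (regular rhythms whose per-bin band power is far
steadier than filtered noise); the gamma carriers are frequency-shaped
Gaussian noise.  Welch spectra of both show band-shaped humps.  Coupling
is injected by amplitude modulation of the high-band carrier,
``(1 + depth*cos(phi_low - phi0))``, using the low carrier's exact phase.
Phase locking is implemented by phase-dependent thinning of a renewal
process, which realizes the exact von Mises conditional phase law.
"""

from __future__ import annotations

import json
import math

import numpy as np
from numpy.random import Generator, SeedSequence, default_rng
from scipy import fft as sp_fft
from scipy import signal
from scipy.special import i0

from .bands import BAND_ORDER, band_edges
from .config import ConfigurationError, SimConfig, UnitSpec
from .session import Session

__all__ = [
    "generate_state_sequence",
    "synthesize_lfp",
    "synthesize_accelerometer",
    "synthesize_spike_train",
    "generate_session",
    "render_wideband",
    "default_waveform_template",
]


# ---------------------------------------------------------------------------
# low-level noise helpers
# ---------------------------------------------------------------------------

def _crossfade_synth(n: int, spectrum_shape: np.ndarray, rng: Generator,
                     chunk: int, overlap: int, analytic: bool) -> np.ndarray:
    """Overlap-add frequency-shaped white-noise chunks with sqrt-ramp
    cross-fades.  ``analytic=True`` zeroes negative frequencies and returns
    complex64 (real part = signal, argument = instantaneous phase);
    otherwise returns the real float32 signal."""
    hop = chunk - overlap
    ramp = np.sqrt(np.linspace(0.0, 1.0, overlap, dtype=np.float32))
    out = np.zeros(n, dtype=np.complex64 if analytic else np.float32)
    start = 0
    while start < n:
        w = rng.standard_normal(chunk).astype(np.float32)
        X = sp_fft.rfft(w)
        X *= spectrum_shape
        if analytic:
            full = np.zeros(chunk, dtype=np.complex64)
            full[: chunk // 2 + 1] = X
            full[1: (chunk + 1) // 2] *= 2.0   # one-sided spectrum
            z = sp_fft.ifft(full, overwrite_x=True)
        else:
            z = sp_fft.irfft(X, n=chunk)
        if start > 0:
            z[:overlap] *= ramp
        if start + chunk < n:
            z[-overlap:] *= ramp[::-1]
        end = min(n, start + chunk)
        out[start:end] += z[: end - start]
        if end == n:
            break
        start += hop
    sd = out.real[: 1 << 22].std()     # sampled estimate is plenty
    if sd > 0:
        out /= sd
    return out


def powerlaw_noise(n: int, alpha: float, rng: Generator, fs: float = 1000.0,
                   chunk: int = 1 << 21) -> np.ndarray:
    """Unit-variance 1/f^alpha noise from spectrally shaped white-noise
    chunks, cross-faded at the seams."""
    chunk = min(chunk, 1 << int(np.ceil(np.log2(max(n, 1024)))))
    f = np.fft.rfftfreq(chunk, 1.0 / fs)
    shape = np.ones_like(f, dtype=np.float32)
    shape[1:] = (f[1:] ** (-alpha / 2.0)).astype(np.float32)
    shape[0] = 0.0
    return _crossfade_synth(n, shape, rng, chunk, min(1 << 14, chunk // 4),
                            analytic=False)


_GAIN_CACHE: dict[tuple, np.ndarray] = {}


def _band_gain(band: str, chunk: int, fs: float) -> np.ndarray:
    """Magnitude response of the band's 2nd-order Butterworth band-pass on
    the rfft grid of one synthesis chunk (cached)."""
    key = (band, chunk, fs)
    if key not in _GAIN_CACHE:
        lo, hi = band_edges(band)
        sos = signal.butter(2, [lo, hi], btype="bandpass", fs=fs, output="sos")
        f = np.fft.rfftfreq(chunk, 1.0 / fs)
        _, resp = signal.sosfreqz(sos, worN=f, fs=fs)
        _GAIN_CACHE[key] = np.abs(resp).astype(np.float32)
    return _GAIN_CACHE[key]


def _band_noise(n: int, band: str, fs: float, rng: Generator,
                analytic: bool = False,
                chunk: int = 1 << 21) -> np.ndarray:
    """Narrowband Gaussian carrier for one canonical band (unit variance).

    White noise is shaped in the frequency domain by the magnitude response
    of a second-order Butterworth band-pass.  With ``analytic=True`` the
    negative frequencies are zeroed and the complex64 analytic carrier is
    returned (real part = carrier, argument = instantaneous phase; sums of
    cross-faded analytic chunks stay analytic).
    """
    chunk = min(chunk, 1 << int(np.ceil(np.log2(max(n, 4096)))))
    gain = _band_gain(band, chunk, fs)
    return _crossfade_synth(n, gain, rng, chunk, min(1 << 14, chunk // 4),
                            analytic=analytic)


def _ou_series(m: int, tau_samples: float, rng: Generator) -> np.ndarray:
    """Unit-variance Ornstein-Uhlenbeck (AR(1)) series."""
    a = math.exp(-1.0 / max(tau_samples, 1.0))
    w = rng.standard_normal(m).astype(np.float32)
    return signal.lfilter([math.sqrt(1.0 - a * a)], [1.0, -a], w).astype(np.float32)


def _upsample_linear(x: np.ndarray, k: int, n: int) -> np.ndarray:
    """Linear interpolation by an integer factor (x is oversampled relative
    to its content, so linear interpolation is accurate)."""
    if k == 1:
        return np.ascontiguousarray(x[:n])
    from ._kernels import upsample_linear
    return upsample_linear(np.ascontiguousarray(x, dtype=np.float32), k, n)


#: bands synthesized as stabilized oscillator sums (the classifier's
#: 0-50 Hz feature range), with the number of components per band; the
#: gamma bands stay filtered-noise carriers
_OSCILLATOR_BANDS = {"delta": 8, "theta": 4, "alpha": 4, "beta": 4}


def _oscillator_carrier(n: int, band: str, fs: float, rng: Generator,
                        amp_cv: float = 0.25, f_tau_s: float = 0.3,
                        a_tau_s: float = 1.0, want_phasor: bool = False,
                        freq_range: tuple[float, float] | None = None):
    """Narrowband carrier as a sum of amplitude-stabilized oscillators.

    Several independent oscillators are pinned at evenly spaced center
    frequencies across the band; each wanders slightly (clipped OU process)
    and carries a slow log-normal amplitude envelope with coefficient of
    variation ``amp_cv``.  This emulates the regular high-amplitude rhythms
    of real cortical oscillations: the per-bin band power and spectral
    shape fluctuate far less than for filtered Gaussian noise, while Welch
    spectra still show a smooth band-shaped hump.  Returns (carrier, unit
    phasor or None); the phasor is the exact analytic phase of the carrier
    (all components have positive frequencies only), so planted
    cross-frequency coupling is exact by construction.
    """
    lo, hi = freq_range or band_edges(band)
    width = hi - lo
    n_comp = _OSCILLATOR_BANDS.get(band, 3)
    dec = max(1, int(fs // (4.0 * hi)))
    r = fs / dec
    m = n // dec + 2
    centers = lo + width * (np.arange(n_comp) + 0.5) / n_comp
    sf = width / (2.0 * n_comp)
    z = np.zeros(m, dtype=np.complex64)
    for fc in centers:
        f_inst = np.clip(fc + sf * _ou_series(m, f_tau_s * r, rng), lo, hi)
        phase = np.cumsum(f_inst, dtype=np.float64) * (2.0 * np.pi / r)
        phase = np.mod(phase, 2.0 * np.pi).astype(np.float32)
        a_env = np.exp(amp_cv * _ou_series(m, a_tau_s * r, rng)
                       - 0.5 * amp_cv * amp_cv)
        z.real += a_env * np.cos(phase)
        z.imag += a_env * np.sin(phase)
    carrier = _upsample_linear(z.real, dec, n)
    sd = carrier[: 1 << 22].std()
    if sd > 0:
        carrier /= sd
    phasor = None
    if want_phasor:
        # keep the unit phasor at the decimated rate; consumers upsample
        # on demand (saves ~0.7 GB per coupled band on a 24-h session)
        z /= np.maximum(np.abs(z), 1e-6)
        phasor = _DecimatedPhasor(z, dec)
    return carrier, phasor


class _DecimatedPhasor:
    """Unit phasor e^{i phi(t)} stored at a decimated rate."""

    def __init__(self, z: np.ndarray, dec: int):
        self.z = z
        self.dec = dec

    def cos(self, n: int) -> np.ndarray:
        return _upsample_linear(self.z.real, self.dec, n)

    def sin(self, n: int) -> np.ndarray:
        return _upsample_linear(self.z.imag, self.dec, n)


def chunked_phase(x: np.ndarray, chunk: int = 1 << 20,
                  pad: int = 1 << 14) -> np.ndarray:
    """Instantaneous Hilbert phase in [0, 2pi), computed chunkwise with
    generous overlap so narrowband edge transients never reach the output."""
    n = len(x)
    out = np.empty(n, dtype=np.float32)
    for s in range(0, n, chunk):
        e = min(n, s + chunk)
        a, b = max(0, s - pad), min(n, e + pad)
        ph = np.angle(signal.hilbert(np.asarray(x[a:b], dtype=np.float64)))
        out[s:e] = ph[s - a:e - a]
    return np.mod(out, 2.0 * np.pi)


def _bin_envelope(per_bin: np.ndarray, bin_samples: int, n: int,
                  fade_samples: int) -> np.ndarray:
    """Expand per-bin values to sample rate with <=1 s linear cross-fades,
    writing ramps only where the value actually changes."""
    vals = np.asarray(per_bin, dtype=np.float32)
    env = np.repeat(vals, bin_samples)[:n]
    if fade_samples > 1:
        half = fade_samples // 2
        t = np.linspace(0.0, 1.0, 2 * half, dtype=np.float32)
        for b in np.flatnonzero(np.diff(vals) != 0):
            c = (b + 1) * bin_samples          # boundary sample
            a, z = max(0, c - half), min(n, c + half)
            if z > a:
                seg = t[(a - (c - half)):(a - (c - half)) + (z - a)]
                env[a:z] = vals[b] + (vals[b + 1] - vals[b]) * seg
    return env


# ---------------------------------------------------------------------------
# state sequence
# ---------------------------------------------------------------------------

def generate_state_sequence(cfg: SimConfig, seed: int | None = None) -> np.ndarray:
    """Semi-Markov per-bin state labels.

    During lights-off the sequence alternates NREM and REM bouts with dwell
    times drawn uniformly from ``cfg.state_dwell``, interrupting cycles with
    brief Rest/Move awakenings with probability ``cfg.awakening_prob``.
    During lights-on, Move and Rest alternate, with short REM naps inserted
    with probability ``cfg.nap_prob``.
    """
    cfg.validate()
    if cfg.session_hours < 1:
        raise ConfigurationError("session_hours must be >= 1")
    rng = default_rng(cfg.seed if seed is None else seed)
    n_bins = cfg.n_bins
    bins_per_hour = 3600.0 / cfg.bin_s
    night_lo = int(cfg.lights_off[0] * bins_per_hour)
    night_hi = int(cfg.lights_off[1] * bins_per_hour)

    def dwell_bins(key: str) -> int:
        lo, hi = cfg.state_dwell[key]
        minutes = rng.uniform(lo, hi)
        return max(1, int(round(minutes * 60.0 / cfg.bin_s)))

    labels = np.empty(n_bins, dtype="<U8")
    t = 0
    night_next = "NREM"
    day_next = "Move"
    while t < n_bins:
        night = night_lo <= t < night_hi
        if night:
            state = night_next
            nb = dwell_bins(state)
            if state == "NREM":
                night_next = "REM"
            else:
                night_next = "NREM"
                if rng.random() < cfg.awakening_prob:
                    labels[t:t + nb] = state
                    t += nb
                    wake = "Rest" if rng.random() < 0.5 else "Move"
                    nb = dwell_bins("awakening")
                    state = wake
        else:
            state = day_next
            nb = dwell_bins(state)
            day_next = "Rest" if state == "Move" else "Move"
            if rng.random() < cfg.nap_prob:
                labels[t:t + nb] = state
                t += nb
                state = "REM"
                nb = dwell_bins("nap")
        labels[t:t + nb] = state
        t += nb
    return labels


# ---------------------------------------------------------------------------
# LFP
# ---------------------------------------------------------------------------

def _structured_channel(states: np.ndarray, cfg: SimConfig, rng: Generator,
                        n: int, bin_samples: int) -> np.ndarray:
    """One channel's structured signal: 1/f background plus state-enveloped
    band carriers with planted phase-amplitude coupling."""
    fs = cfg.lfp_rate
    fade = int(min(1.0, cfg.bin_s / 4) * fs)
    sig = cfg.noise_scale * powerlaw_noise(n, cfg.noise_exponent, rng, fs)

    # per-bin amplitude for each band
    amp_bins = {
        band: np.array([cfg.band_powers[s].get(band, 0.0) for s in states],
                       dtype=np.float32)
        for band in BAND_ORDER
    }
    # per-bin complex coupling coefficient D = depth * exp(i*phi0) keyed by
    # (low, high); state-dependent via the bin labels
    coupling: dict[tuple[str, str], np.ndarray] = {}
    for state, low, high, depth, phi0 in cfg.coupling_spec:
        key = (low, high)
        D = coupling.setdefault(key, np.zeros(len(states), dtype=np.complex64))
        D[states == state] = depth * np.exp(1j * phi0)

    lows_needed = {low for (low, _high) in coupling}
    # unit phasors e^{i phi_low} of the low-band carriers, kept for
    # modulating the coupled high bands (band order is ascending, so lows
    # are always generated before their high partners)
    unit_phasor: dict[str, _DecimatedPhasor] = {}
    for band in BAND_ORDER:
        if not (np.any(amp_bins[band]) or band in lows_needed):
            continue
        if band in _OSCILLATOR_BANDS:
            carrier, phasor = _oscillator_carrier(
                n, band, fs, rng, amp_cv=cfg.carrier_amp_cv,
                want_phasor=band in lows_needed,
                freq_range=cfg.carrier_ranges.get(band))
            if phasor is not None:
                unit_phasor[band] = phasor
        elif band in lows_needed:
            z = _band_noise(n, band, fs, rng, analytic=True)
            carrier = z.real.copy()
            np.divide(z, np.abs(z), out=z)     # in place: z -> e^{i phi}
            unit_phasor[band] = _DecimatedPhasor(z, 1)
            del z
        else:
            carrier = _band_noise(n, band, fs, rng)
        mods = [(low, D) for (low, high), D in coupling.items() if high == band]
        if mods:
            m = np.ones(n, dtype=np.float32)
            for low, D in mods:
                Dr = _bin_envelope(D.real, bin_samples, n, fade)
                Di = _bin_envelope(D.imag, bin_samples, n, fade)
                u = unit_phasor[low]
                # Re(conj(D) e^{i phi}) = depth * cos(phi - phi0)
                m += Dr * u.cos(n)
                m += Di * u.sin(n)
            np.clip(m, 0.0, None, out=m)
            carrier *= m
        carrier *= _bin_envelope(amp_bins[band], bin_samples, n, fade)
        sig += carrier
    return sig


def iter_lfp_channels(states: np.ndarray, cfg: SimConfig,
                      seed: int | None = None):
    """Yield LFP channels one at a time (float32 arrays).

    Streaming lets callers process long sessions channel by channel (e.g.
    accumulate per-bin spectra) without holding the full channels x samples
    matrix in memory.  The channel values are identical to the rows of
    :func:`synthesize_lfp` for the same seed.
    """
    states = np.asarray(states)
    if states.size == 0:
        raise ValueError("states must be nonempty")
    cfg.validate()
    fs = cfg.lfp_rate
    bin_samples = int(round(cfg.bin_s * fs))
    n = len(states) * bin_samples
    seed = cfg.seed if seed is None else seed
    ss = seed if isinstance(seed, SeedSequence) else SeedSequence(seed)
    children = ss.spawn(cfg.n_channels + 1)
    frac = cfg.shared_fraction
    w_common, w_priv = math.sqrt(frac), math.sqrt(1.0 - frac)

    common = None
    if frac > 0:
        common = _structured_channel(states, cfg, default_rng(children[-1]),
                                     n, bin_samples)
    for ch in range(cfg.n_channels):
        if frac >= 1.0:
            yield common.copy()
            continue
        priv = _structured_channel(states, cfg, default_rng(children[ch]),
                                   n, bin_samples)
        if common is not None:
            priv *= w_priv
            priv += w_common * common
        yield priv


def synthesize_lfp(states: np.ndarray, cfg: SimConfig,
                   seed: int | None = None) -> np.ndarray:
    """Synthesize the channels x samples LFP matrix for a state sequence."""
    out = None
    for ch, sig in enumerate(iter_lfp_channels(states, cfg, seed)):
        if out is None:
            out = np.empty((cfg.n_channels, len(sig)), dtype=np.float32)
        out[ch] = sig
    return out


# ---------------------------------------------------------------------------
# accelerometer
# ---------------------------------------------------------------------------

def synthesize_accelerometer(states: np.ndarray, cfg: SimConfig,
                             seed: int | None = None) -> np.ndarray:
    """3-axis acceleration whose per-bin variance is largest during Move,
    intermediate during REM (head movements) and lowest during NREM, with
    Poisson movement bursts superimposed on stationary noise."""
    states = np.asarray(states)
    cfg.validate()
    rng = default_rng(cfg.seed if seed is None else seed)
    fs = cfg.accel_rate
    bin_samples = int(round(cfg.bin_s * fs))
    n = len(states) * bin_samples
    std_bins = np.array([cfg.accel_std[s] for s in states], dtype=np.float32)
    env = np.repeat(std_bins, bin_samples)[:n]
    accel = rng.standard_normal((3, n)).astype(np.float32) * env

    burst_len = int(round(cfg.accel_burst_s * fs))
    if burst_len > 0:
        window = np.hanning(burst_len).astype(np.float32)
        p_bins = np.array(
            [cfg.accel_burst_rate[s] * cfg.bin_s / 60.0 for s in states])
        n_bursts = rng.poisson(p_bins)
        for b in np.flatnonzero(n_bursts):
            amp = 3.0 * cfg.accel_std[states[b]]
            for _ in range(n_bursts[b]):
                start = b * bin_samples + rng.integers(0, bin_samples)
                stop = min(n, start + burst_len)
                w = window[: stop - start]
                accel[:, start:stop] += (
                    amp * w * rng.standard_normal((3, stop - start)).astype(np.float32))
    return accel


# ---------------------------------------------------------------------------
# spikes
# ---------------------------------------------------------------------------

#: ISI-mode hazard bump height and width divisor (sigma = mode/divisor)
_ISI_BUMP = 6.0
_ISI_SDIV = 4.0


def _recovery(delta_ms: np.ndarray, unit: UnitSpec,
              with_bump: bool = True) -> np.ndarray:
    """Relative hazard as a function of time since the last spike: zero
    inside the refractory period, then flat with a Gaussian bump at the
    target ISI mode that shapes the ISI histogram.

    The bump is dropped (``with_bump=False``) in states where the unit
    phase-locks: there the rhythm itself concentrates ISIs near the band
    period, and a time-since-spike bump would bias the realized locked
    phase away from the planted one.
    """
    g = np.ones_like(delta_ms)
    if with_bump:
        m = unit.isi_peak_ms
        s = max(1.0, m / _ISI_SDIV)
        g += _ISI_BUMP * np.exp(-0.5 * ((delta_ms - m) / s) ** 2)
    g[delta_ms < unit.refractory_ms] = 0.0
    return g


def _calibrate_hazard_scale(rate_hz: float, unit: UnitSpec,
                            with_bump: bool = True) -> float:
    """Scale A such that the renewal process with hazard A*g has mean rate
    ``rate_hz`` (solved on a 0.5 ms grid by bisection)."""
    if rate_hz <= 0:
        return 0.0
    horizon_ms = max(2000.0, 20.0 / rate_hz * 1000.0)
    grid = np.arange(0.0, horizon_ms, 0.5)
    g = _recovery(grid, unit, with_bump)
    cum = np.cumsum(g) * 0.5e-3  # integral of g in seconds

    def mean_isi(A: float) -> float:
        surv = np.exp(-A * cum)
        return float(np.sum(surv) * 0.5e-3)

    target = 1.0 / rate_hz
    if mean_isi(1e6) > target:
        raise ConfigurationError(
            f"rate {rate_hz} Hz cannot be honored with refractory "
            f"{unit.refractory_ms} ms")
    lo, hi = 1e-3, 1e6
    for _ in range(60):
        mid = math.sqrt(lo * hi)
        if mean_isi(mid) > target:
            lo = mid
        else:
            hi = mid
    return math.sqrt(lo * hi)


def synthesize_spike_train(states: np.ndarray, lfp: np.ndarray, unit: UnitSpec,
                           cfg: SimConfig, seed: int | None = None) -> np.ndarray:
    """Spike times (s) for one unit via phase-dependent thinning.

    The hazard is ``A(state) * g(t - t_last) * exp(kappa*cos(phi - mu))/I0(kappa)``
    where ``g`` enforces the refractory period and the ISI mode and ``phi``
    is the band-filtered Hilbert phase of the unit's own LFP channel.  The
    von Mises factor has unit mean over uniform phase, so state rates stay
    calibrated, and the conditional spike-phase law is exactly von Mises.
    """
    from .cfc import bandpass_filter  # late import to avoid a cycle

    states = np.asarray(states)
    unit.validate()
    if unit.channel >= lfp.shape[0]:
        raise ConfigurationError("unit channel not present in LFP")
    fs = cfg.lfp_rate
    bin_samples = int(round(cfg.bin_s * fs))
    n = min(lfp.shape[1], len(states) * bin_samples)
    rng = default_rng(cfg.seed if seed is None else seed)

    # ISI-mode bump applies only in states where this unit does not lock
    locked_states = {s for (s, _b, k, _m) in unit.locking if k > 0}
    bump_by_state = {s: s not in locked_states for s in set(states)}
    # per-sample base hazard scale from the per-state calibration
    scale_by_state = {
        s: _calibrate_hazard_scale(unit.base_rate.get(s, 0.0), unit,
                                   with_bump=bump_by_state[s])
        for s in set(states)}
    A_bins = np.array([scale_by_state[s] for s in states], dtype=np.float64)
    A = np.repeat(A_bins, bin_samples)[:n]
    bump_bins = np.array([bump_by_state[s] for s in states], dtype=np.float64)
    bump_on = np.repeat(bump_bins, bin_samples)[:n]

    # von Mises modulation per sample (unit mean over uniform phase)
    lock = np.ones(n, dtype=np.float64)
    lock_max = 1.0
    bands_used = {band for (_s, band, _k, _m) in unit.locking}
    phases = {band: chunked_phase(bandpass_filter(
        np.asarray(lfp[unit.channel, :n], dtype=np.float64), band, fs))
        for band in bands_used}
    for state, band, kappa, mu in unit.locking:
        if kappa == 0:
            continue
        mask = np.repeat(states == state, bin_samples)[:n]
        ph = phases[band][mask]
        lock[mask] = np.exp(kappa * np.cos(ph - mu)) / i0(kappa)
        lock_max = max(lock_max, math.exp(kappa) / i0(kappa))

    g_max = float(_recovery(np.array([unit.isi_peak_ms]), unit)[0])
    lam_max = A.max(initial=0.0) * g_max * lock_max  # dominating hazard, Hz
    if lam_max <= 0:
        return np.empty(0)

    dt = 1.0 / fs
    p = min(1.0, lam_max * dt)
    cand = np.flatnonzero(rng.random(n) < p)
    u = rng.random(len(cand))
    spikes = []
    t_last = -np.inf
    for idx, ui in zip(cand, u):
        delta_ms = (idx - t_last) * dt * 1000.0
        if delta_ms < unit.refractory_ms:
            continue
        g = 1.0 + bump_on[idx] * _ISI_BUMP * math.exp(
            -0.5 * ((delta_ms - unit.isi_peak_ms)
                    / max(1.0, unit.isi_peak_ms / _ISI_SDIV)) ** 2)
        haz = A[idx] * g * lock[idx]
        if ui * lam_max < haz:
            spikes.append(idx)
            t_last = idx
    return np.asarray(spikes, dtype=np.float64) * dt


# ---------------------------------------------------------------------------
# wideband rendering (for spike-discriminator tests)
# ---------------------------------------------------------------------------

def default_waveform_template(rate: float = 20000.0,
                              amplitude: float = 1.0) -> np.ndarray:
    """Biphasic extracellular template: ~0.3 ms negative trough followed by a
    broader positive peak, 1.6 ms total."""
    t = np.arange(int(1.6e-3 * rate)) / rate * 1000.0  # ms
    trough = -np.exp(-0.5 * ((t - 0.35) / 0.10) ** 2)
    peak = 0.45 * np.exp(-0.5 * ((t - 0.80) / 0.22) ** 2)
    w = trough + peak
    return (amplitude * w / np.abs(w).max()).astype(np.float64)


def render_wideband(spike_times: np.ndarray, duration_s: float,
                    template: np.ndarray | None = None,
                    rate: float = 20000.0, noise_std: float = 0.1,
                    lfp: np.ndarray | None = None, lfp_rate: float = 1000.0,
                    lfp_gain: float = 1.0,
                    seed: int | None = None) -> np.ndarray:
    """20 kHz-like wideband trace: scaled LFP + white noise + the waveform
    template inserted at each spike time."""
    rng = default_rng(seed)
    n = int(round(duration_s * rate))
    trace = rng.standard_normal(n) * noise_std
    if lfp is not None:
        up = int(round(rate / lfp_rate))
        trace[: len(lfp) * up] += lfp_gain * np.repeat(
            np.asarray(lfp, dtype=np.float64), up)[:n]
    if template is None:
        template = default_waveform_template(rate)
    for t in np.asarray(spike_times, dtype=np.float64):
        i = int(round(t * rate))
        j = min(n, i + len(template))
        if i < n:
            trace[i:j] += template[: j - i]
    return trace


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

def generate_session(cfg: SimConfig) -> Session:
    """Generate a complete synthetic session (deterministic given cfg.seed)."""
    cfg.validate()
    ss = SeedSequence(cfg.seed)
    s_states, s_lfp, s_accel, s_eog, *s_units = ss.spawn(4 + len(cfg.units))
    states = generate_state_sequence(cfg, seed=s_states)
    lfp = synthesize_lfp(states, cfg, seed=s_lfp)
    accel = synthesize_accelerometer(states, cfg, seed=s_accel)
    spike_times = [
        synthesize_spike_train(states, lfp, u, cfg, seed=s)
        for u, s in zip(cfg.units, s_units)
    ]
    eog = None
    if cfg.with_eog:
        rng = default_rng(s_eog)
        std = {"Move": 1.0, "Rest": 0.8, "REM": 0.5, "NREM": 0.08}
        bin_samples = int(round(cfg.bin_s * cfg.lfp_rate))
        env = np.repeat(np.array([std[s] for s in states], dtype=np.float32),
                        bin_samples)
        eog = rng.standard_normal((2, len(env))).astype(np.float32) * env
    unit_meta = [
        {"unit_type": u.unit_type, "isi_peak_ms": u.isi_peak_ms,
         "channel": u.channel, "refractory_ms": u.refractory_ms}
        for u in cfg.units
    ]
    sess = Session(
        lfp=lfp, accel=accel, eog=eog,
        lfp_rate=cfg.lfp_rate, accel_rate=cfg.accel_rate, bin_s=cfg.bin_s,
        lights_off=cfg.lights_off, truth_states=states,
        spike_times=spike_times, unit_meta=unit_meta,
        config_json=json.dumps(cfg.to_dict(), default=float), seed=cfg.seed,
    )
    sess.validate()
    return sess
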