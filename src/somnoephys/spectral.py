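"""Per-bin Welch spectra, classifier feature normalization, and per-state
channel-pair coherence / weighted phase lag index.

The classifier features are the 0-50 Hz Welch PSD of each non-overlapping
8-s bin (2-s Hann segments, 50% overlap, 0.5 Hz grid -> 101 points),
averaged over channels and normalized per bin by subtracting the minimum
and dividing by the integral, so relative band power dominates absolute
gain.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy import fft as sp_fft
from scipy import signal

from .bands import BANDS

__all__ = [
    "SpectralEstimate",
    "CoherenceSpectrum",
    "downsample_to_1khz",
    "welch_psd_per_bin",
    "normalize_mean_psd",
    "magnitude_squared_coherence",
    "weighted_phase_lag_index",
]


@dataclass
class SpectralEstimate:
    freqs: np.ndarray                 # Hz, strictly increasing
    psd: np.ndarray                   # channels x bins x freqs, power per Hz
    band_edges: dict = None

    def __post_init__(self):
        if self.band_edges is None:
            self.band_edges = dict(BANDS)


@dataclass
class CoherenceSpectrum:
    freqs: np.ndarray
    cxy: np.ndarray
    wpli: np.ndarray | None = None
    n_segments: int = 0


def downsample_to_1khz(x: np.ndarray, rate: float) -> np.ndarray:
    """Anti-alias (450 Hz low-pass) and resample to 1000 Hz.

    Identity when the input is already at 1 kHz; rates below 1 kHz are
    rejected rather than upsampled.
    """
    if rate < 1000:
        raise ValueError("input rate must be >= 1000 Hz")
    if rate == 1000:
        return x
    sos = signal.butter(8, 450.0, btype="low", fs=rate, output="sos")
    y = signal.sosfiltfilt(sos, x, axis=-1)
    frac = Fraction(1000, 1) / Fraction(rate).limit_denominator(10**6)
    up, down = frac.numerator, frac.denominator
    if up == 1:
        return np.ascontiguousarray(y[..., ::down])
    return signal.resample_poly(y, up, down, axis=-1)


def welch_psd_per_bin(lfp_1khz: np.ndarray, fs: float = 1000.0,
                      bin_s: float = 8.0, fmax: float | None = 50.0,
                      seg_s: float = 2.0) -> SpectralEstimate:
    """Welch PSD of each non-overlapping bin (one-sided density).

    Uses ``seg_s``-second Hann segments with 50% overlap inside each bin
    (seven segments for the 8-s default).  ``fmax=None`` retains the full
    one-sided range.
    """
    x = np.atleast_2d(np.asarray(lfp_1khz))
    bin_samples = int(round(bin_s * fs))
    nperseg = int(round(seg_s * fs))
    if bin_samples < nperseg:
        raise ValueError("bin shorter than one Welch segment")
    n_bins = x.shape[1] // bin_samples
    if n_bins < 1:
        raise ValueError("need at least one full bin of samples")
    xb = x[:, : n_bins * bin_samples].reshape(x.shape[0], n_bins, bin_samples)

    freqs = np.fft.rfftfreq(nperseg, 1.0 / fs)
    keep = slice(None) if fmax is None else slice(0, int(np.searchsorted(freqs, fmax, "right")))
    freqs = freqs[keep]
    hop = nperseg // 2
    n_segs = (bin_samples - nperseg) // hop + 1
    win = signal.get_window("hann", nperseg).astype(np.float32)
    scale = 1.0 / (fs * float(np.sum(win.astype(np.float64) ** 2)))
    psd = np.empty((x.shape[0], n_bins, len(freqs)))
    chunk = max(1, int(1.2e8 // (x.shape[0] * n_segs * nperseg * 8)))
    for b0 in range(0, n_bins, chunk):
        b1 = min(n_bins, b0 + chunk)
        segs = np.lib.stride_tricks.sliding_window_view(
            xb[:, b0:b1], nperseg, axis=-1)[..., ::hop, :]
        segs = segs.astype(np.float32)
        segs -= segs.mean(axis=-1, keepdims=True)      # constant detrend
        segs *= win
        X = sp_fft.rfft(segs, axis=-1)[..., keep]
        p = (X.real.astype(np.float64) ** 2
             + X.imag.astype(np.float64) ** 2).mean(axis=2)
        p *= 2.0 * scale                               # one-sided density
        if freqs[0] == 0.0:
            p[..., 0] /= 2.0
        if fmax is None and nperseg % 2 == 0:
            p[..., -1] /= 2.0                          # Nyquist not doubled
        psd[:, b0:b1] = p
    return SpectralEstimate(freqs=freqs, psd=psd)


def normalize_mean_psd(estimate: SpectralEstimate) -> np.ndarray:
    """Per-bin classifier feature vectors (bins x freqs).

    Average the PSD across channels, then per bin subtract the minimum and
    divide by the trapezoidal integral over frequency, so every feature
    vector has min 0 and unit integral.
    """
    psd = estimate.psd
    if psd.ndim != 3 or psd.shape[0] < 1:
        raise ValueError("psd must be channels x bins x freqs")
    mean = psd.mean(axis=0)
    mean = mean - mean.min(axis=1, keepdims=True)
    integral = np.trapezoid(mean, estimate.freqs, axis=1)
    if np.any(integral <= 0):
        raise ValueError("degenerate (all-zero) bin cannot be normalized")
    return mean / integral[:, None]


# ---------------------------------------------------------------------------
# coherence / wPLI from same-state contiguous stretches
# ---------------------------------------------------------------------------

def _mask_runs(mask: np.ndarray | None, n: int):
    if mask is None:
        return [(0, n)]
    mask = np.asarray(mask, dtype=bool)
    edges = np.flatnonzero(np.diff(np.concatenate(([0], mask.view(np.int8), [0]))))
    return list(zip(edges[::2], edges[1::2]))


def _segment_cross_accum(x, y, fs, state_mask, seg_s, fmax):
    """Accumulate Welch cross/auto spectra and Im(Sxy) statistics over
    50%-overlapping Hann segments drawn from contiguous masked stretches."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    nperseg = int(round(seg_s * fs))
    hop = nperseg // 2
    win = np.hanning(nperseg)
    freqs = np.fft.rfftfreq(nperseg, 1.0 / fs)
    keep = slice(None) if fmax is None else slice(0, int(np.searchsorted(freqs, fmax, "right")))
    freqs = freqs[keep]
    s_xy = np.zeros(len(freqs), dtype=np.complex128)
    s_xx = np.zeros(len(freqs))
    s_yy = np.zeros(len(freqs))
    s_im = np.zeros(len(freqs))
    s_absim = np.zeros(len(freqs))
    nseg = 0
    for a, b in _mask_runs(state_mask, len(x)):
        for s in range(a, b - nperseg + 1, hop):
            xs = x[s:s + nperseg]
            ys = y[s:s + nperseg]
            X = np.fft.rfft((xs - xs.mean()) * win)[keep]
            Y = np.fft.rfft((ys - ys.mean()) * win)[keep]
            Sxy = X * np.conj(Y)
            s_xy += Sxy
            s_xx += (X.real**2 + X.imag**2)
            s_yy += (Y.real**2 + Y.imag**2)
            s_im += Sxy.imag
            s_absim += np.abs(Sxy.imag)
            nseg += 1
    if nseg < 2:
        raise ValueError("need at least 2 segments of state-contiguous data")
    return freqs, s_xy, s_xx, s_yy, s_im, s_absim, nseg


def magnitude_squared_coherence(x, y, fs: float = 1000.0,
                                state_mask: np.ndarray | None = None,
                                seg_s: float = 10.0,
                                fmax: float | None = 120.0) -> CoherenceSpectrum:
    """Cxy = |Pxy|^2 / (Pxx * Pyy) on a 0.1 Hz grid (10-s Hann segments),
    estimated from contiguous same-state stretches only."""
    freqs, s_xy, s_xx, s_yy, *_rest, nseg = _segment_cross_accum(
        x, y, fs, state_mask, seg_s, fmax)
    denom = s_xx * s_yy
    cxy = np.zeros_like(s_xx)
    nz = denom > 0
    cxy[nz] = np.abs(s_xy[nz]) ** 2 / denom[nz]
    return CoherenceSpectrum(freqs=freqs, cxy=np.clip(cxy, 0.0, 1.0),
                             n_segments=nseg)


def weighted_phase_lag_index(x, y, fs: float = 1000.0,
                             state_mask: np.ndarray | None = None,
                             seg_s: float = 10.0,
                             fmax: float | None = 120.0) -> CoherenceSpectrum:
    """wPLI = |mean Im(Sxy)| / mean |Im(Sxy)| over segments; zero-lag
    (volume-conducted) coupling contributes nothing to the numerator."""
    freqs, s_xy, s_xx, s_yy, s_im, s_absim, nseg = _segment_cross_accum(
        x, y, fs, state_mask, seg_s, fmax)
    wpli = np.zeros_like(s_im)
    # an imaginary cross-spectrum that is pure floating-point residue of a
    # real one (zero-lag mixtures) must count as zero, not as phase lag
    nz = s_absim > 1e-9 * np.abs(s_xy)
    wpli[nz] = np.abs(s_im[nz]) / s_absim[nz]
    denom = s_xx * s_yy
    cxy = np.zeros_like(s_xx)
    pos = denom > 0
    cxy[pos] = np.abs(s_xy[pos]) ** 2 / denom[pos]
    return CoherenceSpectrum(freqs=freqs, cxy=np.clip(cxy, 0.0, 1.0),
                             wpli=np.clip(wpli, 0.0, 1.0), n_segments=nseg)
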