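"""Band filtering, analytic signals, and cross-frequency phase-amplitude
coupling via the normalized mean vector length (nMVL).

The coupling statistic is the mean vector length ``MVL = |mean(r e^{i phi})|``
where ``phi`` is the instantaneous phase of the lower band and ``r`` the
instantaneous amplitude of the higher band.  Because MVL scales with
amplitude, it is normalized by the maximum possible MVL for the same state:
the highest amplitudes are re-paired with the most commonly occurring
phases (so the largest vectors all point in similar directions) and the
mean vector recomputed; nMVL = MVL / maxMVL is gain-invariant and lies in
[0, 1].

Phase convention: 0 is the oscillation peak and pi the trough.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import signal

from .bands import band_center, band_edges, band_pairs

logger = logging.getLogger(__name__)

__all__ = [
    "AnalyticSeries",
    "CouplingEstimate",
    "bandpass_filter",
    "analytic_signal",
    "coupling_estimate",
    "phase_power_map",
    "coupling_table",
]

#: filter transients excluded from coupling statistics (seconds per edge)
EDGE_EXCLUDE_S = 1.0


@dataclass
class AnalyticSeries:
    phase: np.ndarray        # radians in [0, 2pi); 0 = peak, pi = trough
    amplitude: np.ndarray    # same units as the input signal
    fs: float = 1000.0
    band: str | None = None


@dataclass
class CouplingEstimate:
    low_band: str | None
    high_band: str | None
    state: str | None
    mvl: float
    max_mvl: float
    nmvl: float
    mean_phase: float
    n: int
    channel: int | None = None


def bandpass_filter(x: np.ndarray, band: str | tuple[float, float],
                    fs: float = 1000.0) -> np.ndarray:
    """Zero-phase second-order Butterworth band-pass (applied forward and
    backward, so the effective magnitude response is fourth order)."""
    lo, hi = band_edges(band) if isinstance(band, str) else band
    if hi >= fs / 2:
        raise ValueError(f"band edge {hi} Hz is at/above Nyquist ({fs / 2} Hz)")
    sos = signal.butter(2, [lo, hi], btype="bandpass", fs=fs, output="sos")
    return signal.sosfiltfilt(sos, x, axis=-1)


def analytic_signal(filtered: np.ndarray, fs: float = 1000.0,
                    band: str | None = None) -> AnalyticSeries:
    """Hilbert analytic signal: phase (0 = peak of the oscillation, wrapped
    to [0, 2pi)) and amplitude envelope."""
    x = np.asarray(filtered, dtype=np.float64)
    if not np.all(np.isfinite(x)):
        raise ValueError("signal must be finite")
    if np.ptp(x) == 0:
        raise ValueError("constant signal has undefined phase")
    h = signal.hilbert(x)
    return AnalyticSeries(phase=np.mod(np.angle(h), 2.0 * np.pi),
                          amplitude=np.abs(h), fs=fs, band=band)


def _select(phase, amplitude, state_mask, fs, edge_exclude_s):
    phase = np.asarray(phase)
    amplitude = np.asarray(amplitude)
    if phase.shape != amplitude.shape:
        raise ValueError("phase and amplitude must be the same length")
    keep = np.ones(len(phase), dtype=bool)
    edge = int(round(edge_exclude_s * fs))
    if edge > 0 and 2 * edge < len(phase):
        keep[:edge] = False
        keep[-edge:] = False
    if state_mask is not None:
        keep &= np.asarray(state_mask, dtype=bool)[: len(keep)]
    if not np.any(keep):
        raise ValueError("no samples selected by the state mask")
    return phase[keep], amplitude[keep]


def max_possible_mvl(phase: np.ndarray, amplitude: np.ndarray,
                     n_phase_bins: int = 64) -> float:
    """Maximum attainable MVL under amplitude-to-phase reassignment.

    Phases are histogrammed into equal bins; samples are reordered so that
    phases from denser bins come first (order within a bin is arbitrary) and
    are paired with amplitudes sorted descending, concentrating the largest
    vectors around the most common phases.
    """
    edges = np.linspace(0.0, 2.0 * np.pi, n_phase_bins + 1)
    which = np.clip(np.digitize(phase, edges) - 1, 0, n_phase_bins - 1)
    counts = np.bincount(which, minlength=n_phase_bins)
    density_rank = np.argsort(-counts, kind="stable")
    rank_of_bin = np.empty(n_phase_bins, dtype=np.int64)
    rank_of_bin[density_rank] = np.arange(n_phase_bins)
    order = np.argsort(rank_of_bin[which], kind="stable")
    amp_sorted = np.sort(amplitude)[::-1]
    vec = np.mean(amp_sorted * np.exp(1j * phase[order]))
    return float(np.abs(vec))


def coupling_estimate(low_phase: np.ndarray, high_amplitude: np.ndarray,
                      state_mask: np.ndarray | None = None,
                      fs: float = 1000.0, n_phase_bins: int = 64,
                      edge_exclude_s: float = EDGE_EXCLUDE_S,
                      low_band: str | None = None, high_band: str | None = None,
                      state: str | None = None) -> CouplingEstimate:
    """MVL, max-possible MVL, normalized MVL and mean-vector phase for one
    (low band phase, high band amplitude) pair within one state."""
    if (low_band is not None and high_band is not None
            and band_center(low_band) >= band_center(high_band)):
        raise ValueError("low band center must be below high band center")
    phi, r = _select(low_phase, high_amplitude, state_mask, fs, edge_exclude_s)
    vec = np.mean(r * np.exp(1j * phi))
    mvl = float(np.abs(vec))
    mean_phase = float(np.mod(np.angle(vec), 2.0 * np.pi))
    max_mvl = max_possible_mvl(phi, r, n_phase_bins)
    # a vanishing max-MVL (uniform phases with near-constant amplitude)
    # means no pairing could produce coupling: define nMVL as 0
    if max_mvl <= 1e-9 * float(np.mean(r)):
        nmvl = 0.0
    else:
        nmvl = mvl / max_mvl
    if nmvl > 1.0:
        logger.warning("nMVL %.6f > 1 (heuristic max-MVL pairing); clamping",
                       nmvl)
    nmvl = float(np.clip(nmvl, 0.0, 1.0))
    return CouplingEstimate(low_band=low_band, high_band=high_band,
                            state=state, mvl=mvl, max_mvl=max_mvl,
                            nmvl=nmvl, mean_phase=mean_phase, n=len(phi))


def phase_power_map(low_phase: np.ndarray, high_power: np.ndarray,
                    n_phase_bins: int = 36) -> tuple[np.ndarray, np.ndarray]:
    """Mean high-frequency power per low-band phase bin, z-scored across
    phase bins for each frequency row.

    ``high_power`` may be 1-D (one frequency/band) or rows x samples.
    Returns (phase bin centers, rows x n_phase_bins matrix); empty phase
    bins are NaN.
    """
    power = np.atleast_2d(np.asarray(high_power, dtype=np.float64))
    phase = np.asarray(low_phase)
    if power.shape[1] != len(phase):
        raise ValueError("power and phase lengths differ")
    edges = np.linspace(0.0, 2.0 * np.pi, n_phase_bins + 1)
    which = np.clip(np.digitize(phase, edges) - 1, 0, n_phase_bins - 1)
    counts = np.bincount(which, minlength=n_phase_bins)
    out = np.full((power.shape[0], n_phase_bins), np.nan)
    for b in range(n_phase_bins):
        if counts[b]:
            out[:, b] = power[:, which == b].mean(axis=1)
    mean = np.nanmean(out, axis=1, keepdims=True)
    std = np.nanstd(out, axis=1, keepdims=True)
    std[std == 0] = 1.0
    centers = 0.5 * (edges[:-1] + edges[1:])
    return centers, (out - mean) / std


def coupling_table(lfp: np.ndarray, states: np.ndarray, fs: float = 1000.0,
                   bin_s: float = 8.0,
                   pairs: list[tuple[str, str]] | None = None,
                   which_states: list[str] | None = None,
                   min_samples: int = 10_000) -> list[CouplingEstimate]:
    """Per-channel coupling estimates for every (low, high) band pair and
    state.  States with fewer than ``min_samples`` in-state samples are
    skipped."""
    lfp = np.atleast_2d(lfp)
    states = np.asarray(states)
    pairs = pairs or band_pairs()
    which_states = which_states or sorted(set(states))
    bin_samples = int(round(bin_s * fs))
    n = lfp.shape[1]
    masks = {}
    for s in which_states:
        m = np.repeat(states == s, bin_samples)[:n]
        if m.sum() >= min_samples:
            masks[s] = m
    out: list[CouplingEstimate] = []
    bands_needed = sorted({b for p in pairs for b in p})
    for ch in range(lfp.shape[0]):
        x = np.asarray(lfp[ch], dtype=np.float64)
        analytic = {b: analytic_signal(bandpass_filter(x, b, fs), fs, b)
                    for b in bands_needed}
        for low, high in pairs:
            for s, m in masks.items():
                est = coupling_estimate(
                    analytic[low].phase, analytic[high].amplitude,
                    state_mask=m, fs=fs, low_band=low, high_band=high, state=s)
                est.channel = ch
                out.append(est)
    return out
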