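"""Spike-LFP synchrony: phase-locking value, locked phase, spike
phase-by-amplitude distributions, and the spike-count bias analysis.

The phase-locking value converts the band-filtered LFP phase at each spike
time into a unit vector and takes the magnitude of the average,
``PLV = |1/n sum exp(i phi)|``: 0 for uniform phases, 1 for perfect
locking.  The locked phase is the circular mean ``arg(sum exp(i phi))``.
PLV is positively biased at small spike counts (E[PLV] = sqrt(pi)/(2 sqrt(n))
for uniform phases), which becomes inconsequential beyond ~10,000 spikes;
estimates below that count carry a ``low_n`` flag.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.random import default_rng
from scipy.special import i0, i1

from .cfc import AnalyticSeries

__all__ = [
    "PhaseLockingEstimate",
    "phase_locking_value",
    "spike_phase_amplitude_distribution",
    "plv_bias_curve",
    "von_mises_plv",
    "blank_spikes",
]

LOW_N_THRESHOLD = 10_000
MIN_SPIKES = 50


@dataclass
class PhaseLockingEstimate:
    plv: float
    locked_phase: float              # radians in [0, 2pi)
    n_spikes: int
    low_n: bool
    unit: int | None = None
    band: str | None = None
    state: str | None = None


def von_mises_plv(kappa: float) -> float:
    """Population resultant length of a von Mises distribution,
    I1(kappa)/I0(kappa) — the large-n PLV of locked spikes."""
    if kappa == 0:
        return 0.0
    return float(i1(kappa) / i0(kappa))


def _spike_phases(spike_times, analytic: AnalyticSeries, state_mask):
    """Phase at the nearest LFP sample to each (in-state) spike."""
    t = np.asarray(spike_times, dtype=np.float64)
    idx = np.round(t * analytic.fs).astype(int)
    valid = (idx >= 0) & (idx < len(analytic.phase))
    idx = idx[valid]
    if state_mask is not None:
        mask = np.asarray(state_mask, dtype=bool)
        idx = idx[mask[idx]]
    return analytic.phase[idx], idx


def phase_locking_value(spike_times: np.ndarray, analytic: AnalyticSeries,
                        state_mask: np.ndarray | None = None,
                        unit: int | None = None, band: str | None = None,
                        state: str | None = None) -> PhaseLockingEstimate:
    """PLV and circular-mean locked phase of in-state spikes against the
    band phase of the unit's own channel."""
    phases, _ = _spike_phases(spike_times, analytic, state_mask)
    n = len(phases)
    if n == 0:
        raise ValueError("no in-state spikes")
    if n < MIN_SPIKES:
        raise ValueError(f"need at least {MIN_SPIKES} spikes, got {n}")
    vec = np.sum(np.exp(1j * phases))
    return PhaseLockingEstimate(
        plv=float(np.abs(vec) / n),
        locked_phase=float(np.mod(np.angle(vec), 2.0 * np.pi)),
        n_spikes=n, low_n=bool(n < LOW_N_THRESHOLD),
        unit=unit, band=band or analytic.band, state=state)


def spike_phase_amplitude_distribution(spike_times: np.ndarray,
                                       analytic: AnalyticSeries,
                                       state_mask: np.ndarray | None = None,
                                       n_phase: int = 36, n_amp: int = 10
                                       ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Spike-phase histograms per amplitude decile.

    Spikes are assigned to (phase bin, amplitude-decile) cells using the
    band amplitude at spike times; each amplitude row is normalized to sum
    one (empty rows are NaN).  Returns (phase bin centers, amplitude decile
    edges, n_amp x n_phase matrix).
    """
    phases, idx = _spike_phases(spike_times, analytic, state_mask)
    if len(phases) == 0:
        raise ValueError("no in-state spikes")
    amps = analytic.amplitude[idx]
    amp_edges = np.quantile(amps, np.linspace(0, 1, n_amp + 1))
    ph_edges = np.linspace(0.0, 2.0 * np.pi, n_phase + 1)
    which_amp = np.clip(np.searchsorted(amp_edges, amps, side="right") - 1,
                        0, n_amp - 1)
    which_ph = np.clip(np.digitize(phases, ph_edges) - 1, 0, n_phase - 1)
    out = np.full((n_amp, n_phase), np.nan)
    for a in range(n_amp):
        row = np.bincount(which_ph[which_amp == a], minlength=n_phase)
        if row.sum() > 0:
            out[a] = row / row.sum()
    centers = 0.5 * (ph_edges[:-1] + ph_edges[1:])
    return centers, amp_edges, out


def plv_bias_curve(kappa: float, n_grid: np.ndarray, reps: int = 100,
                   seed: int = 0) -> dict:
    """Monte-Carlo expected PLV and its small-sample bias versus spike
    count, for spikes with von Mises(kappa) phases.

    ``bias = E[PLV] - I1(kappa)/I0(kappa)``; for kappa=0 the expectation
    follows sqrt(pi)/(2 sqrt(n)).
    """
    n_grid = np.asarray(n_grid, dtype=int)
    if reps < 10:
        raise ValueError("need at least 10 Monte-Carlo repetitions")
    if np.any(np.diff(n_grid) <= 0):
        raise ValueError("n_grid must be increasing")
    rng = default_rng(seed)
    asymptote = von_mises_plv(kappa)
    expected = np.empty(len(n_grid))
    for i, n in enumerate(n_grid):
        phases = rng.vonmises(0.0, kappa, size=(reps, n))
        expected[i] = np.mean(np.abs(np.mean(np.exp(1j * phases), axis=1)))
    return {
        "n": n_grid,
        "expected_plv": expected,
        "bias": expected - asymptote,
        "asymptote": asymptote,
    }


def blank_spikes(lfp: np.ndarray, spike_times: np.ndarray, fs: float = 1000.0,
                 half_ms: float = 2.0) -> np.ndarray:
    """Linearly interpolate the LFP across +/-``half_ms`` around each spike.

    Optional pre-filtering step (off by default in every analysis): spike
    waveforms bleed into the gamma bands of the same channel, which can
    inflate spike-field locking estimates; blanking removes the transient
    at the cost of briefly distorting the LFP.
    """
    x = np.asarray(lfp, dtype=np.float64).copy()
    half = int(round(half_ms * 1e-3 * fs))
    n = len(x)
    for t in np.asarray(spike_times, dtype=np.float64):
        i = int(round(t * fs))
        a, b = max(0, i - half), min(n - 1, i + half)
        if b > a:
            x[a:b + 1] = np.linspace(x[a], x[b], b - a + 1)
    return x
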