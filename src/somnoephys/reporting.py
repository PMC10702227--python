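"""State-wise statistical comparisons and end-to-end pipeline orchestration.

Paired per-state values (channels or units as rows, the four states as
columns) are compared with Friedman's test; pairwise differences are
resolved post hoc with a rank-based Tukey/Nemenyi procedure on the
Friedman mean ranks, using the studentized range distribution.
Significance is p < 0.05 throughout.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .bands import BANDS, STATES, band_pairs
from .cfc import analytic_signal, bandpass_filter, coupling_table
from .classifier import ClassificationResult, classify_session, kfold_validate
from .config import AutoencoderConfig, SimConfig
from .session import Session
from .spectral import magnitude_squared_coherence, weighted_phase_lag_index
from .spike_field import phase_locking_value
from .spikes import profile_unit
from .synthetic import generate_session

logger = logging.getLogger(__name__)

__all__ = ["StateComparison", "friedman_with_posthoc", "PipelineConfig",
           "run_pipeline"]


@dataclass
class StateComparison:
    measure: str
    values: np.ndarray                  # rows x states (paired design)
    state_names: tuple[str, ...]
    friedman_chi2: float
    friedman_p: float
    pairwise_p: np.ndarray              # states x states
    significant: np.ndarray             # boolean, p < 0.05


def friedman_with_posthoc(values: np.ndarray, measure: str = "",
                          state_names: tuple[str, ...] = STATES,
                          alpha: float = 0.05) -> StateComparison:
    """Friedman test across the four states with rank-based Tukey-style
    post-hoc pairwise comparisons.

    ``values`` is rows (units/channels, paired) x 4 states, no missing
    cells.  Post hoc: mean within-row ranks compared with the studentized
    range distribution (Nemenyi procedure).
    """
    X = np.asarray(values, dtype=np.float64)
    if X.ndim != 2 or X.shape[1] != len(state_names):
        raise ValueError(
            f"need a rows x {len(state_names)} matrix of paired values")
    if X.shape[1] < 3:
        raise ValueError("Friedman design requires at least 3 states")
    if X.shape[0] < 5:
        raise ValueError("need at least 5 paired rows")
    if not np.all(np.isfinite(X)):
        raise ValueError("missing cells in paired design")
    n, k = X.shape
    chi2, p = stats.friedmanchisquare(*(X[:, j] for j in range(k)))
    ranks = stats.rankdata(X, axis=1)
    mean_ranks = ranks.mean(axis=0)
    se = np.sqrt(k * (k + 1) / (6.0 * n))
    pw = np.ones((k, k))
    for a in range(k):
        for b in range(a + 1, k):
            q = abs(mean_ranks[a] - mean_ranks[b]) / se
            pv = stats.studentized_range.sf(q * np.sqrt(2.0), k, np.inf)
            pw[a, b] = pw[b, a] = float(np.clip(pv, 0.0, 1.0))
    return StateComparison(
        measure=measure, values=X, state_names=tuple(state_names),
        friedman_chi2=float(chi2), friedman_p=float(p),
        pairwise_p=pw, significant=(pw < alpha) & ~np.eye(k, dtype=bool))


# ---------------------------------------------------------------------------
# end-to-end pipeline
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    sim: SimConfig = field(default_factory=SimConfig)
    ae: AutoencoderConfig | None = None
    out_dir: str = "results"
    seed: int = 0
    validate_k: int = 20
    validate_reps: int = 0              # 0 skips k-fold validation
    with_coherence: bool = True
    coherence_max_pairs: int = 4
    with_cfc: bool = True
    cfc_pairs: list[tuple[str, str]] | None = None
    with_spikes: bool = True

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        sim = SimConfig.from_dict(d.pop("sim")) if "sim" in d else SimConfig()
        ae = AutoencoderConfig(**d.pop("ae")) if "ae" in d else None
        cfg = cls(sim=sim, ae=ae, **d)
        if cfg.cfc_pairs is not None:
            cfg.cfc_pairs = [tuple(p) for p in cfg.cfc_pairs]
        return cfg


def _states_csv(result: ClassificationResult, bin_s: float, path: Path):
    pd.DataFrame({
        "bin_start_s": np.arange(len(result.states)) * bin_s,
        "state": result.states,
        "raw_cluster": result.cluster_ids,
    }).to_csv(path, index=False)


def _coherence_frame(session: Session, states, max_pairs: int) -> pd.DataFrame:
    rows = []
    n_ch = session.n_channels
    pairs = [(a, b) for a in range(n_ch) for b in range(a + 1, n_ch)][:max_pairs]
    for s in sorted(set(states)):
        mask = session.state_sample_mask(s, states=states)
        for a, b in pairs:
            try:
                spec = weighted_phase_lag_index(
                    session.lfp[a], session.lfp[b], fs=session.lfp_rate,
                    state_mask=mask)
            except ValueError:
                continue
            for band, (lo, hi) in BANDS.items():
                m = (spec.freqs >= lo) & (spec.freqs <= hi)
                rows.append({
                    "state": s, "channel_a": a, "channel_b": b, "band": band,
                    "median_coherence": float(np.median(spec.cxy[m])),
                    "median_wpli": float(np.median(spec.wpli[m])),
                })
    return pd.DataFrame(rows)


def _cfc_frame(session: Session, states, pairs) -> pd.DataFrame:
    ests = coupling_table(session.lfp, states, fs=session.lfp_rate,
                          bin_s=session.bin_s, pairs=pairs)
    return pd.DataFrame([{
        "state": e.state, "low_band": e.low_band, "high_band": e.high_band,
        "channel": e.channel, "mvl": e.mvl, "max_mvl": e.max_mvl,
        "nmvl": e.nmvl, "mean_phase": e.mean_phase,
    } for e in ests])


def _spike_frames(session: Session, states) -> tuple[pd.DataFrame, pd.DataFrame]:
    unit_rows, plv_rows = [], []
    analytic_cache: dict[tuple[int, str], object] = {}
    for u, spike_times in enumerate(session.spike_times):
        meta = session.unit_meta[u] if u < len(session.unit_meta) else {}
        if len(spike_times) < 2:
            continue
        prof = profile_unit(spike_times, states, session.bin_s)
        row = {"unit": u, "class": prof.unit_class,
               "isi_peak_ms": prof.isi_peak_ms}
        for s in STATES:
            row[f"rate_{s.lower()}"] = prof.state_rates.get(s, np.nan)
        unit_rows.append(row)
        ch = int(meta.get("channel", 0))
        for band in BANDS:
            key = (ch, band)
            if key not in analytic_cache:
                analytic_cache[key] = analytic_signal(
                    bandpass_filter(np.asarray(session.lfp[ch], np.float64),
                                    band, session.lfp_rate),
                    session.lfp_rate, band)
            for s in sorted(set(states)):
                mask = session.state_sample_mask(s, states=states)
                try:
                    est = phase_locking_value(spike_times,
                                              analytic_cache[key],
                                              state_mask=mask, unit=u,
                                              band=band, state=s)
                except ValueError:
                    continue
                plv_rows.append({
                    "unit": u, "class": prof.unit_class, "band": band,
                    "state": s, "plv": est.plv,
                    "locked_phase": est.locked_phase,
                    "n_spikes": est.n_spikes, "low_n": est.low_n,
                })
    return pd.DataFrame(unit_rows), pd.DataFrame(plv_rows)


def _comparisons(cfc: pd.DataFrame, plv: pd.DataFrame) -> dict:
    out = {}
    if len(cfc):
        for (low, high), grp in cfc.groupby(["low_band", "high_band"]):
            piv = grp.pivot(index="channel", columns="state", values="nmvl")
            if piv.shape[0] >= 5 and not piv.isna().any().any() \
                    and piv.shape[1] == 4:
                piv = piv[[s for s in STATES if s in piv.columns]]
                cmp_ = friedman_with_posthoc(piv.to_numpy(),
                                             measure=f"nmvl {low}->{high}",
                                             state_names=tuple(piv.columns))
                out[f"nmvl_{low}_{high}"] = {
                    "chi2": cmp_.friedman_chi2, "p": cmp_.friedman_p,
                    "significant_pairs": [
                        [cmp_.state_names[a], cmp_.state_names[b]]
                        for a in range(4) for b in range(a + 1, 4)
                        if cmp_.significant[a, b]],
                }
    if len(plv):
        for band, grp in plv.groupby("band"):
            piv = grp.pivot(index="unit", columns="state", values="plv")
            if piv.shape[0] >= 5 and not piv.isna().any().any() \
                    and piv.shape[1] == 4:
                cmp_ = friedman_with_posthoc(piv.to_numpy(),
                                             measure=f"plv {band}",
                                             state_names=tuple(piv.columns))
                out[f"plv_{band}"] = {
                    "chi2": cmp_.friedman_chi2, "p": cmp_.friedman_p,
                    "significant_pairs": [
                        [cmp_.state_names[a], cmp_.state_names[b]]
                        for a in range(4) for b in range(a + 1, 4)
                        if cmp_.significant[a, b]],
                }
    return out


def run_pipeline(config: PipelineConfig, session: Session | None = None) -> dict:
    """Simulate (unless a session is given), classify, validate, and run the
    coupling/spike/spike-field analyses; write CSVs plus a JSON summary to
    ``config.out_dir`` and return the summary dict."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    summary: dict = {"seed": config.seed}
    try:
        if session is None:
            logger.info("generating synthetic session")
            session = generate_session(config.sim)
            summary["sim_seed"] = config.sim.seed
        logger.info("classifying session")
        result = classify_session(session, ae_cfg=config.ae, seed=config.seed)
        states = result.states
        _states_csv(result, session.bin_s, out_dir / "states.csv")
        summary["occupancy"] = result.occupancy
        summary["low_occupancy_flags"] = result.low_occupancy_flags
        if session.truth_states is not None:
            summary["accuracy_vs_truth"] = result.accuracy_vs(session.truth_states)
            summary["recall_vs_truth"] = result.recall_vs(session.truth_states)
        if config.validate_reps > 0:
            logger.info("k-fold validation")
            summary["validation"] = {
                k: v for k, v in kfold_validate(
                    session, k=config.validate_k, reps=config.validate_reps,
                    seed=config.seed, reference=result, ae_cfg=config.ae,
                ).items() if not k.startswith("per_fold")}
        cfc_df = pd.DataFrame()
        plv_df = pd.DataFrame()
        if config.with_coherence:
            logger.info("coherence / wPLI")
            coh = _coherence_frame(session, states, config.coherence_max_pairs)
            coh.to_csv(out_dir / "coherence.csv", index=False)
        if config.with_cfc:
            logger.info("cross-frequency coupling")
            cfc_df = _cfc_frame(session, states,
                                config.cfc_pairs or band_pairs())
            cfc_df.to_csv(out_dir / "cfc.csv", index=False)
        if config.with_spikes and session.spike_times:
            logger.info("spike and spike-field analyses")
            units_df, plv_df = _spike_frames(session, states)
            units_df.to_csv(out_dir / "units.csv", index=False)
            plv_df.to_csv(out_dir / "plv.csv", index=False)
        summary["comparisons"] = _comparisons(cfc_df, plv_df)
    except Exception as exc:  # re-raise with the failing stage attached
        raise RuntimeError(f"pipeline failed: {exc}") from exc
    with open(out_dir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, default=float)
    return summary
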