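"""Unsupervised four-state classification of 8-s bins.

Pipeline: normalized per-bin PSD features -> stacked sparse autoencoder
(32-d latent) -> head-acceleration feature appended as a 33rd dimension ->
k-means (k=4) with outlier-excluded initialization -> rule-based cluster
labeling (Move by acceleration, NREM by delta, Rest by beta, REM remaining)
-> +/-2-bin majority smoothing.  Self-validation is k-fold: retrain on
k-1 groups, classify the held-out group by nearest centroid, and score
disagreement with the all-data classification.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.random import default_rng
from scipy.spatial.distance import cdist
from sklearn.cluster import KMeans

from .autoencoder import Autoencoder, encode_features, train_autoencoder
from .bands import band_edges
from .config import AutoencoderConfig
from .session import Session
from .spectral import downsample_to_1khz, normalize_mean_psd, welch_psd_per_bin

__all__ = [
    "accelerometer_feature",
    "build_latent_table",
    "kmeans_cluster",
    "label_clusters",
    "majority_filter",
    "classify_session",
    "kfold_validate",
    "ClassificationResult",
]


def accelerometer_feature(accel: np.ndarray, accel_rate: float,
                          bin_s: float = 8.0,
                          n_bins: int | None = None) -> np.ndarray:
    """Raw per-bin accelerometer feature: log10 of the within-bin variance
    of the root-sum-of-squares across the three axes.

    Zero-variance bins are floored at machine epsilon before the log.
    Centering and scaling against the latent columns happens in
    :func:`build_latent_table`.
    """
    accel = np.asarray(accel)
    if accel.ndim != 2 or accel.shape[0] != 3:
        raise ValueError("accel must be 3 x samples")
    rss = np.sqrt(np.sum(accel.astype(np.float64) ** 2, axis=0))
    bin_samples = int(round(bin_s * accel_rate))
    nb = len(rss) // bin_samples
    if n_bins is not None:
        if nb < n_bins:
            raise ValueError("accelerometer does not cover all bins")
        nb = n_bins
    var = rss[: nb * bin_samples].reshape(nb, bin_samples).var(axis=1)
    var = np.maximum(var, np.finfo(np.float64).eps)
    return np.log10(var)


def build_latent_table(latent: np.ndarray, accel_raw: np.ndarray,
                       stat_idx: np.ndarray | None = None) -> np.ndarray:
    """Append the accelerometer feature as the 33rd column: centered to zero
    mean and rescaled so its std equals the largest latent-column std.
    ``stat_idx`` restricts the bins used for the statistics (k-fold training
    bins) while the transform is applied to every bin."""
    latent = np.asarray(latent, dtype=np.float64)
    accel_raw = np.asarray(accel_raw, dtype=np.float64)
    if len(latent) != len(accel_raw):
        raise ValueError("latent and accelerometer feature lengths differ")
    idx = slice(None) if stat_idx is None else stat_idx
    target_std = latent[idx].std(axis=0).max()
    mu = accel_raw[idx].mean()
    sd = accel_raw[idx].std()
    col = (accel_raw - mu) * (target_std / sd if sd > 0 else 0.0)
    return np.column_stack([latent, col])


def kmeans_cluster(latent_table: np.ndarray, k: int = 4, seed: int = 0,
                   n_init: int = 10, fit_idx: np.ndarray | None = None
                   ) -> tuple[np.ndarray, np.ndarray]:
    """k-means with outlier-excluded initialization.

    Centroids are found using only points whose mean pairwise Euclidean
    distance to all points is within the 90th percentile (k-means++
    seeding, ``n_init`` restarts, best inertia kept); every point is then
    assigned to its nearest centroid.  Returns (labels, centroids).
    """
    X = np.asarray(latent_table, dtype=np.float64)
    fit_X = X if fit_idx is None else X[fit_idx]
    if len(np.unique(fit_X, axis=0)) < k:
        raise ValueError(f"need at least {k} distinct points")
    # mean pairwise distance per point, chunked to bound memory
    n = len(fit_X)
    mean_d = np.empty(n)
    chunk = max(1, int(2e8 // (8 * n)))
    for s in range(0, n, chunk):
        mean_d[s:s + chunk] = cdist(fit_X[s:s + chunk], fit_X).mean(axis=1)
    core = fit_X[mean_d <= np.percentile(mean_d, 90.0)]
    km = KMeans(n_clusters=k, init="k-means++", n_init=n_init,
                random_state=seed).fit(core)
    centroids = km.cluster_centers_
    labels = cdist(X, centroids).argmin(axis=1)
    return labels, centroids


def label_clusters(clusters: np.ndarray, features: np.ndarray,
                   accel_feature: np.ndarray, freqs: np.ndarray,
                   stat_idx: np.ndarray | None = None
                   ) -> tuple[np.ndarray, dict[int, str]]:
    """Assign the four states to clusters by sequential argmax with removal:
    highest mean acceleration -> Move, then highest mean delta power ->
    NREM, then highest mean beta power -> Rest, remaining -> REM."""
    clusters = np.asarray(clusters)
    ids = np.unique(clusters)
    if len(ids) != 4:
        raise ValueError(f"expected exactly 4 clusters, got {len(ids)}")
    idx = np.arange(len(clusters)) if stat_idx is None else np.asarray(stat_idx)
    d_lo, d_hi = band_edges("delta")
    b_lo, b_hi = band_edges("beta")
    delta_m = (freqs >= d_lo) & (freqs <= d_hi)
    beta_m = (freqs >= b_lo) & (freqs <= b_hi)
    stats = {}
    for c in ids:
        members = idx[clusters[idx] == c]
        if len(members) == 0:
            raise ValueError(f"cluster {c} is empty")
        stats[c] = (
            accel_feature[members].mean(),
            features[members][:, delta_m].mean(),
            features[members][:, beta_m].mean(),
        )
    remaining = list(ids)
    mapping: dict[int, str] = {}
    for state, key in (("Move", 0), ("NREM", 1), ("Rest", 2)):
        pick = max(remaining, key=lambda c: stats[c][key])
        mapping[pick] = state
        remaining.remove(pick)
    mapping[remaining[0]] = "REM"
    states = np.array([mapping[c] for c in clusters], dtype="<U8")
    return states, mapping


def majority_filter(states: np.ndarray, seed: int = 0) -> np.ndarray:
    """Sliding +/-2-bin majority smoothing (truncated windows at the ends).

    Ties keep the original label when it is part of the tie, otherwise a
    seeded random choice among the tied labels.
    """
    states = np.asarray(states)
    rng = default_rng(seed)
    n = len(states)
    out = states.copy()
    for i in range(n):
        window = states[max(0, i - 2): i + 3]
        labels, counts = np.unique(window, return_counts=True)
        top = labels[counts == counts.max()]
        if len(top) == 1:
            out[i] = top[0]
        elif states[i] in top:
            out[i] = states[i]
        else:
            out[i] = rng.choice(top)
    return out


@dataclass
class ClassificationResult:
    states: np.ndarray                       # smoothed per-bin labels
    raw_states: np.ndarray                   # pre-majority-filter labels
    cluster_ids: np.ndarray
    cluster_to_state: dict[int, str]
    features: np.ndarray                     # bins x freqs
    freqs: np.ndarray
    latent: np.ndarray                       # bins x 32
    accel_raw: np.ndarray
    centroids: np.ndarray
    encoder: Autoencoder
    occupancy: dict[str, float] = field(default_factory=dict)
    state_mean_spectra: dict[str, np.ndarray] = field(default_factory=dict)
    low_occupancy_flags: list[str] = field(default_factory=list)

    def accuracy_vs(self, truth: np.ndarray) -> float:
        truth = np.asarray(truth)
        return float(np.mean(self.states[: len(truth)] == truth[: len(self.states)]))

    def recall_vs(self, truth: np.ndarray) -> dict[str, float]:
        truth = np.asarray(truth)[: len(self.states)]
        out = {}
        for s in np.unique(truth):
            m = truth == s
            out[str(s)] = float(np.mean(self.states[m] == s))
        return out


def compute_features(session: Session):
    """Classifier inputs from a session: (features, freqs, accel_raw)."""
    lfp = downsample_to_1khz(session.lfp, session.lfp_rate)
    est = welch_psd_per_bin(lfp, fs=1000.0, bin_s=session.bin_s)
    features = normalize_mean_psd(est)
    accel_raw = accelerometer_feature(session.accel, session.accel_rate,
                                      session.bin_s, n_bins=len(features))
    return features, est.freqs, accel_raw


def classify_features(features: np.ndarray, freqs: np.ndarray,
                      accel_raw: np.ndarray,
                      ae_cfg: AutoencoderConfig | None = None,
                      seed: int = 0) -> ClassificationResult:
    """Classification chain from precomputed per-bin features onward:
    autoencoder -> latent table -> k-means -> labeling -> majority filter."""
    ae_cfg = ae_cfg or AutoencoderConfig(seed=seed)
    encoder = train_autoencoder(features, ae_cfg)
    latent = encode_features(encoder, features)
    table = build_latent_table(latent, accel_raw)
    cluster_ids, centroids = kmeans_cluster(table, k=4, seed=seed)
    raw_states, mapping = label_clusters(cluster_ids, features, accel_raw,
                                         freqs)
    states = majority_filter(raw_states, seed=seed)
    occupancy = {s: float(np.mean(states == s)) for s in np.unique(states)}
    spectra = {s: features[states == s].mean(axis=0) for s in occupancy}
    flags = [s for s, f in occupancy.items() if f < 0.02]
    return ClassificationResult(
        states=states, raw_states=raw_states, cluster_ids=cluster_ids,
        cluster_to_state=mapping, features=features, freqs=freqs,
        latent=latent, accel_raw=accel_raw, centroids=centroids,
        encoder=encoder, occupancy=occupancy, state_mean_spectra=spectra,
        low_occupancy_flags=flags)


def classify_session(session: Session, ae_cfg: AutoencoderConfig | None = None,
                     seed: int = 0) -> ClassificationResult:
    """Run the full classification chain on a session and return the state
    sequence with diagnostics (per-state mean spectra, occupancy)."""
    if session.duration_s < 3600:
        raise ValueError("session must be at least 1 h long")
    features, freqs, accel_raw = compute_features(session)
    return classify_features(features, freqs, accel_raw, ae_cfg=ae_cfg,
                             seed=seed)


def _fold_classify(features, freqs, accel_raw, train_idx, ae_cfg, seed):
    """Retrain the pipeline on the training bins and label every bin (train
    bins by the fold k-means assignment, held-out bins by nearest centroid),
    then re-apply the majority filter on the full timeline."""
    encoder = train_autoencoder(features[train_idx], ae_cfg)
    latent = encode_features(encoder, features)
    table = build_latent_table(latent, accel_raw, stat_idx=train_idx)
    cluster_ids, _ = kmeans_cluster(table, k=4, seed=seed, fit_idx=train_idx)
    raw_states, _ = label_clusters(cluster_ids, features, accel_raw, freqs,
                                   stat_idx=train_idx)
    return majority_filter(raw_states, seed=seed)


def kfold_validate(session: Session | None = None, k: int = 20, reps: int = 50,
                   seed: int = 0, reference: ClassificationResult | None = None,
                   ae_cfg: AutoencoderConfig | None = None,
                   folds_per_rep: int = 1, bin_s: float | None = None) -> dict:
    """k-fold self-consistency of the classification.

    Each repetition splits the bins into ``k`` random groups, retrains the
    full pipeline on k-1 of them and classifies the held-out group by
    nearest centroid.  Training/test error is the percent disagreement with
    the all-data classification on training/held-out bins, averaged over
    folds and repetitions, reported in percent and in total minutes.
    """
    if reference is None:
        if session is None:
            raise ValueError("need a session or a reference classification")
        reference = classify_session(session, ae_cfg=ae_cfg, seed=seed)
    if bin_s is None:
        bin_s = session.bin_s if session is not None else 8.0
    features, freqs = reference.features, reference.freqs
    accel_raw = reference.accel_raw
    n = len(features)
    if k > n:
        raise ValueError("k cannot exceed the number of bins")
    ref_states = reference.states
    rng = default_rng(seed)
    train_errs, test_errs = [], []
    for rep in range(reps):
        order = rng.permutation(n)
        groups = np.array_split(order, k)
        fold_ids = range(min(folds_per_rep, k))
        for f in fold_ids:
            test_idx = np.sort(groups[f])
            train_mask = np.ones(n, dtype=bool)
            train_mask[test_idx] = False
            train_idx = np.flatnonzero(train_mask)
            fold_seed = int(rng.integers(0, 2**31 - 1))
            cfg = ae_cfg or AutoencoderConfig()
            fold_cfg = AutoencoderConfig(
                **{**cfg.__dict__, "seed": fold_seed})
            fold_states = _fold_classify(features, freqs, accel_raw,
                                         train_idx, fold_cfg, fold_seed)
            train_errs.append(
                100.0 * np.mean(fold_states[train_idx] != ref_states[train_idx]))
            test_errs.append(
                100.0 * np.mean(fold_states[test_idx] != ref_states[test_idx]))
    bin_min = bin_s / 60.0
    return {
        "training_error_pct": float(np.mean(train_errs)),
        "test_error_pct": float(np.mean(test_errs)),
        "training_error_min": float(np.mean(train_errs) / 100.0 * n * bin_min),
        "test_error_min": float(np.mean(test_errs) / 100.0 * n * bin_min),
        "per_fold_training_pct": [float(e) for e in train_errs],
        "per_fold_test_pct": [float(e) for e in test_errs],
        "k": k, "reps": reps, "n_bins": n,
    }
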