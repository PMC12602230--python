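"""Voxel-wise local feature maps and population-level habitat discovery.

Each lesion voxel is summarized by 19 first-order statistics of its 5x5x5
physical neighbourhood.  Voxels pooled across the training cohort are
standardized and clustered with K-means; the cluster count is chosen by
consensus over three validity indices (Calinski-Harabasz, Davies-Bouldin,
Silhouette) evaluated for k in a searched range, each k refit with multiple
random seeds.  The fitted model (scaler + centers) is frozen and applied to
unseen patients by nearest-center assignment, so habitat labels are
comparable across patients and cohorts.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.optimize import linear_sum_assignment
from sklearn.cluster import KMeans
from sklearn.metrics import (
    calinski_harabasz_score,
    davies_bouldin_score,
    silhouette_score,
)

from .core import LabelMask, Volume

__all__ = [
    "CHANNEL_NAMES",
    "LocalFeatureMap",
    "HabitatModel",
    "local_features",
    "select_k",
    "fit_habitats",
    "assign_habitats",
    "pairwise_consistency",
]

#: The 19 per-voxel neighbourhood statistics, in output column order.
CHANNEL_NAMES: tuple[str, ...] = (
    "mean",
    "median",
    "sd",
    "variance",
    "min",
    "max",
    "range",
    "p10",
    "p25",
    "p75",
    "p90",
    "skewness",
    "kurtosis",
    "energy",
    "entropy",
    "uniformity",
    "mad",
    "rms",
    "gradient_magnitude",
)

_ENTROPY_BINS = 32


@dataclass
class LocalFeatureMap:
    """Per-voxel local features for one lesion.

    ``features`` is (n_voxels, 19) aligned with ``voxel_indices`` (n_voxels,
    3 array indices into the source grid).
    """

    features: np.ndarray
    voxel_indices: np.ndarray
    channel_names: tuple[str, ...]
    grid_shape: tuple[int, int, int]
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float]
    window: int

    @property
    def n_voxels(self) -> int:
        return self.features.shape[0]


def local_features(volume: Volume, mask: LabelMask, window: int = 5) -> LocalFeatureMap:
    """Compute the 19-channel local feature map on lesion voxels.

    The full ``window**3`` neighbourhood is used (it may extend outside the
    lesion); windows are truncated at image borders.
    """
    if window < 3 or window % 2 == 0:
        raise ValueError("window must be an odd integer >= 3")
    if not volume.same_geometry(mask):
        raise ValueError("volume and mask grids are not aligned")
    m = mask.bool_array()
    if not m.any():
        raise ValueError("mask is empty")
    r = window // 2

    grad = _gradient_magnitude(volume.values, volume.spacing)

    idx = np.argwhere(m)
    lo = idx.min(axis=0)
    hi = idx.max(axis=0) + 1
    shape = np.array(volume.shape)
    crop_lo = np.maximum(lo - r, 0)
    crop_hi = np.minimum(hi + r, shape)
    sl = tuple(slice(a, b) for a, b in zip(crop_lo, crop_hi))
    pad = [((lo - r) - crop_lo)[d] * 0 + int(max(r - lo[d], 0)) for d in range(3)]
    pad_hi = [int(max(hi[d] + r - shape[d], 0)) for d in range(3)]
    pad_spec = [(pad[d], pad_hi[d]) for d in range(3)]

    def padded(a: np.ndarray) -> np.ndarray:
        return np.pad(a[sl].astype(np.float64), pad_spec, constant_values=np.nan)

    img_p = padded(volume.values)
    grad_p = padded(grad)

    # Window views for every voxel of the (expanded, clipped) bbox; select
    # the lesion voxels.
    win_img = np.lib.stride_tricks.sliding_window_view(img_p, (window,) * 3)
    win_grad = np.lib.stride_tricks.sliding_window_view(grad_p, (window,) * 3)
    # Index of each lesion voxel into the window view: window view position p
    # corresponds to padded-array voxel p + r.
    rel = idx - crop_lo + np.array(pad) - r
    W = win_img[rel[:, 0], rel[:, 1], rel[:, 2]].reshape(len(idx), -1)
    G = win_grad[rel[:, 0], rel[:, 1], rel[:, 2]].reshape(len(idx), -1)

    feats = _window_statistics(W, G)
    return LocalFeatureMap(
        features=feats,
        voxel_indices=idx,
        channel_names=CHANNEL_NAMES,
        grid_shape=volume.shape,
        spacing=volume.spacing,
        origin=volume.origin,
        window=window,
    )


def _gradient_magnitude(values: np.ndarray, spacing) -> np.ndarray:
    pads = [np.gradient(values, s, axis=d) for d, s in enumerate(spacing)]
    return np.sqrt(sum(g * g for g in pads))


def _window_statistics(W: np.ndarray, G: np.ndarray) -> np.ndarray:
    """Vectorized 19 statistics per row of W (NaN marks truncated voxels)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        n_valid = np.sum(~np.isnan(W), axis=1).astype(float)
        mean = np.nanmean(W, axis=1)
        median = np.nanmedian(W, axis=1)
        var = np.nanvar(W, axis=1)
        sd = np.sqrt(var)
        mn = np.nanmin(W, axis=1)
        mx = np.nanmax(W, axis=1)
        rng = mx - mn
        p10, p25, p75, p90 = np.nanpercentile(W, [10, 25, 75, 90], axis=1)
        d = W - mean[:, None]
        m2 = var
        m3 = np.nanmean(d**3, axis=1)
        m4 = np.nanmean(d**4, axis=1)
        ok = m2 > 1e-24
        skew = np.where(ok, m3 / np.where(ok, m2, 1.0) ** 1.5, 0.0)
        kurt = np.where(ok, m4 / np.where(ok, m2, 1.0) ** 2 - 3.0, 0.0)
        energy = np.nanmean(W**2, axis=1)
        rms = np.sqrt(energy)
        mad = np.nanmean(np.abs(d), axis=1)
        entropy, uniformity = _window_entropy(W, mn, rng, n_valid)
        gradmag = np.nanmean(G, axis=1)
    return np.column_stack(
        [mean, median, sd, var, mn, mx, rng, p10, p25, p75, p90, skew, kurt,
         energy, entropy, uniformity, mad, rms, gradmag]
    )


def _window_entropy(W, mn, rng, n_valid):
    """Per-row 32-bin histogram entropy (bits) and uniformity (sum p^2)."""
    n_rows = W.shape[0]
    safe_rng = np.where(rng > 0, rng, 1.0)
    levels = np.floor((W - mn[:, None]) / safe_rng[:, None] * _ENTROPY_BINS)
    levels = np.clip(levels, 0, _ENTROPY_BINS - 1)
    valid = ~np.isnan(W)
    rows = np.broadcast_to(np.arange(n_rows)[:, None], W.shape)
    flat = (rows[valid] * _ENTROPY_BINS + levels[valid].astype(np.int64))
    counts = np.bincount(flat, minlength=n_rows * _ENTROPY_BINS).reshape(
        n_rows, _ENTROPY_BINS
    )
    p = counts / n_valid[:, None]
    nz = p > 0
    entropy = -np.sum(np.where(nz, p * np.log2(np.where(nz, p, 1.0)), 0.0), axis=1)
    uniformity = np.sum(p**2, axis=1)
    entropy = np.where(rng > 0, entropy, 0.0)
    uniformity = np.where(rng > 0, uniformity, 1.0)
    return entropy, uniformity


# --------------------------------------------------------------------------
# Population clustering


@dataclass
class HabitatModel:
    """Frozen population habitat definition: scaler + K-means centers."""

    k: int
    centers: np.ndarray  # (k, n_channels) in standardized space
    scaler_mean: np.ndarray
    scaler_sd: np.ndarray
    channel_names: tuple[str, ...]
    k_diagnostics: dict = field(default_factory=dict)
    seeds_used: list[int] = field(default_factory=list)
    consistency: float = float("nan")
    dropped_channels: list[str] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(
            {
                "k": self.k,
                "centers": self.centers.tolist(),
                "scaler_mean": self.scaler_mean.tolist(),
                "scaler_sd": self.scaler_sd.tolist(),
                "channel_names": list(self.channel_names),
                "k_diagnostics": {str(k): v for k, v in self.k_diagnostics.items()},
                "seeds_used": self.seeds_used,
                "consistency": self.consistency,
                "dropped_channels": self.dropped_channels,
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "HabitatModel":
        d = json.loads(text)
        return cls(
            k=d["k"],
            centers=np.asarray(d["centers"]),
            scaler_mean=np.asarray(d["scaler_mean"]),
            scaler_sd=np.asarray(d["scaler_sd"]),
            channel_names=tuple(d["channel_names"]),
            k_diagnostics={int(k): v for k, v in d["k_diagnostics"].items()},
            seeds_used=d["seeds_used"],
            consistency=d["consistency"],
            dropped_channels=d["dropped_channels"],
        )


def select_k(
    voxel_features: np.ndarray,
    k_range: range | tuple[int, int] = (3, 10),
    n_seeds: int = 10,
    base_seed: int = 0,
) -> tuple[int, dict]:
    """Choose the cluster count by consensus of three validity indices.

    For each k in ``k_range`` (inclusive bounds) K-means is fit ``n_seeds``
    times; Calinski-Harabasz, Davies-Bouldin and Silhouette scores are
    computed on the best-inertia fit.  Ranks (Silhouette and CH maximal, DB
    minimal) are averaged; the best mean rank wins, ties going to smaller k.

    Returns ``(k_star, diagnostics)`` where diagnostics maps k to the three
    scores.
    """
    X = np.asarray(voxel_features, dtype=float)
    if isinstance(k_range, range):
        ks = list(k_range)
    else:
        ks = list(range(int(k_range[0]), int(k_range[1]) + 1))
    if not ks:
        raise ValueError("empty k_range")
    n = X.shape[0]
    if min(ks) < 2 or max(ks) > n - 1:
        raise ValueError(f"k_range {ks[0]}..{ks[-1]} outside [2, n_rows-1] for n={n}")
    if np.unique(X, axis=0).shape[0] < max(ks):
        raise ValueError("fewer distinct rows than max k")

    diagnostics: dict[int, dict[str, float]] = {}
    for k in ks:
        best = None
        for s in range(n_seeds):
            km = KMeans(n_clusters=k, n_init=1, random_state=base_seed + s)
            km.fit(X)
            if best is None or km.inertia_ < best.inertia_:
                best = km
        labels = best.labels_
        diagnostics[k] = {
            "calinski_harabasz": float(calinski_harabasz_score(X, labels)),
            "davies_bouldin": float(davies_bouldin_score(X, labels)),
            "silhouette": float(silhouette_score(X, labels)),
            "inertia": float(best.inertia_),
        }

    def ranks(values, maximize):
        order = np.argsort(values)[::-1] if maximize else np.argsort(values)
        r = np.empty(len(values))
        r[order] = np.arange(len(values))
        return r

    sil = [diagnostics[k]["silhouette"] for k in ks]
    ch = [diagnostics[k]["calinski_harabasz"] for k in ks]
    db = [diagnostics[k]["davies_bouldin"] for k in ks]
    mean_rank = (ranks(sil, True) + ranks(ch, True) + ranks(db, False)) / 3.0
    best_rank = mean_rank.min()
    k_star = min(k for k, r in zip(ks, mean_rank) if r == best_rank)
    if max(sil) < 0.5:
        diagnostics["weak_structure"] = True  # type: ignore[index]
    return k_star, diagnostics


def subsample_voxels(
    maps: list[LocalFeatureMap], per_patient: int | None, seed: int = 0
) -> np.ndarray:
    """Pool (optionally per-patient subsampled) voxel features across patients."""
    rng = np.random.default_rng(seed)
    parts = []
    for fm in maps:
        X = fm.features
        if per_patient is not None and X.shape[0] > per_patient:
            sel = rng.choice(X.shape[0], per_patient, replace=False)
            X = X[sel]
        parts.append(X)
    return np.vstack(parts)


def fit_habitats(
    maps: list[LocalFeatureMap] | np.ndarray,
    k: int,
    n_seeds: int = 10,
    subsample_per_patient: int | None = 2000,
    seed: int = 0,
) -> HabitatModel:
    """Fit the population habitat model on training-cohort voxels only.

    Channels are standardized by the training mean/SD (zero-SD channels are
    dropped with a warning); K-means is run ``n_seeds`` times and the
    best-inertia centers kept.  ``consistency`` is the mean over seed pairs
    of the voxel-assignment agreement after optimal (Hungarian) label
    matching.
    """
    if isinstance(maps, np.ndarray):
        X = maps
        names = tuple(f"f{i}" for i in range(X.shape[1]))
    else:
        X = subsample_voxels(maps, subsample_per_patient, seed=seed)
        names = maps[0].channel_names
    X = np.asarray(X, dtype=float)
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    dropped = [names[i] for i in range(len(names)) if sd[i] <= 1e-12]
    if dropped:
        warnings.warn(f"dropping zero-variance channels: {dropped}")
    keep = sd > 1e-12
    Z = (X[:, keep] - mu[keep]) / sd[keep]

    runs = []
    best = None
    for s in range(n_seeds):
        km = KMeans(n_clusters=k, n_init=1, random_state=seed + s)
        km.fit(Z)
        runs.append(km.labels_)
        if best is None or km.inertia_ < best.inertia_:
            best = km
    consistency = pairwise_consistency(runs, k)

    return HabitatModel(
        k=k,
        centers=best.cluster_centers_,
        scaler_mean=mu[keep],
        scaler_sd=sd[keep],
        channel_names=tuple(n for n, kp in zip(names, keep) if kp),
        seeds_used=list(range(seed, seed + n_seeds)),
        consistency=consistency,
        dropped_channels=dropped,
    )


def pairwise_consistency(labelings: list[np.ndarray], k: int) -> float:
    """Mean pairwise agreement after optimal label matching.

    For each pair of labelings the k x k contingency table is matched with
    the Hungarian algorithm to maximize agreement; the metric is invariant
    to label permutations.
    """
    if len(labelings) < 2:
        return 1.0
    n = len(labelings[0])
    agreements = []
    for i in range(len(labelings)):
        for j in range(i + 1, len(labelings)):
            C = np.zeros((k, k))
            np.add.at(C, (labelings[i], labelings[j]), 1)
            r, c = linear_sum_assignment(-C)
            agreements.append(C[r, c].sum() / n)
    return float(np.mean(agreements))


def assign_habitats(model: HabitatModel, fmap: LocalFeatureMap) -> LabelMask:
    """Nearest-center habitat assignment (labels 1..k, 0 outside the lesion).

    Deterministic; ties go to the lowest label index.  Applies a frozen
    training-cohort model to any patient without refitting.
    """
    name_index = {n: i for i, n in enumerate(fmap.channel_names)}
    missing = [n for n in model.channel_names if n not in name_index]
    if missing:
        raise ValueError(f"feature map lacks channels required by the model: {missing}")
    cols = [name_index[n] for n in model.channel_names]
    Z = (fmap.features[:, cols] - model.scaler_mean) / model.scaler_sd
    d2 = ((Z[:, None, :] - model.centers[None, :, :]) ** 2).sum(axis=2)
    labels = np.argmin(d2, axis=1) + 1

    out = np.zeros(fmap.grid_shape, dtype=np.int32)
    out[tuple(fmap.voxel_indices.T)] = labels
    return LabelMask(out, fmap.spacing, fmap.origin)
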