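"""Permutation-based significance for classifier performance and weights.

Labels are permuted uniformly at random (feature rows untouched), the full
leave-one-subject-out cross-validation is rerun per replicate, and p-values
count how often a permuted metric is equal to or higher than the observed
one, divided by the number of permutations.  A count of zero is reported as
"p < 1/n_perm" rather than 0.

Per-voxel significance uses the *normalized* absolute across-fold mean
weight — each run's |mean weight| vector divided by its L2 norm — as the
contribution statistic.  Normalization is essential: a well-separated
observed problem yields a wide margin and hence small raw weights, while
permuted labels force narrow margins and large raw weights, so raw |w|
comparisons are confounded by scale; the normalized statistic compares the
spatial distribution of weight instead.  Surviving voxels (p < alpha) are
grouped into connected components and only components strictly larger than
the extent threshold (default 30 voxels) become discriminative-map clusters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .mvpa import CVResult, FeatureMatrix, features_to_map, losocv

__all__ = [
    "PermutationResult",
    "ClusterROI",
    "DiscriminativeMap",
    "permute_performance",
    "permute_voxel_weights",
    "weight_contribution",
    "extract_clusters",
    "clusters_to_label_map",
    "clusters_from_label_map",
    "build_discriminative_map",
    "format_p",
]

#: Metrics whose permutation nulls are tracked (subset present per task).
TRACKED_METRICS = (
    "total_accuracy",
    "balanced_accuracy",
    "sensitivity",
    "specificity",
    "auc",
)


def weight_contribution(weights: np.ndarray) -> np.ndarray:
    """Per-voxel contribution statistic: |w| as a share of the map's L2 norm."""
    w = np.abs(np.asarray(weights, dtype=np.float64))
    norm = np.linalg.norm(w)
    return w / norm if norm > 0 else w


def format_p(count: int, n_perm: int) -> str:
    """Human-readable permutation p: 'p < 1/n_perm' when no null reaches it."""
    if count == 0:
        return f"p < {1.0 / n_perm:g}"
    return f"p = {count / n_perm:g}"


@dataclass
class PermutationResult:
    """Observed metrics, their permutation nulls, and p-values."""

    observed: dict
    null_values: dict[str, np.ndarray]
    n_perm: int
    seed: int
    p_values: dict[str, float] = field(init=False)
    p_strings: dict[str, str] = field(init=False)
    null_weights: np.ndarray | None = None  # (n_perm, V) |mean weight| nulls

    def __post_init__(self) -> None:
        self.p_values = {}
        self.p_strings = {}
        for name, null in self.null_values.items():
            obs = self.observed[name]
            count = int(np.sum(null >= obs))
            self.p_values[name] = count / self.n_perm
            self.p_strings[name] = format_p(count, self.n_perm)


def permute_performance(
    features: FeatureMatrix,
    labels: np.ndarray,
    algorithm: str = "svm",
    n_perm: int = 1000,
    seed: int = 0,
    collect_weights: bool = False,
    observed: CVResult | None = None,
    **cv_kwargs,
) -> tuple[PermutationResult, CVResult]:
    """Label-permutation null for LOSOCV performance metrics.

    Each replicate draws a uniform permutation of the labels (class counts
    preserved by construction), reruns the complete cross-validation, and
    records the tracked metrics; ``collect_weights`` additionally stores
    each replicate's normalized absolute mean weight vector (the
    :func:`weight_contribution` statistic) for voxelwise inference.
    Deterministic given ``seed``.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    labels = np.asarray(labels)
    if observed is None:
        observed = losocv(features, labels, algorithm=algorithm, **cv_kwargs)
    tracked = [m for m in TRACKED_METRICS if m in observed.metrics]
    nulls = {m: np.empty(n_perm) for m in tracked}
    null_w = (
        np.empty((n_perm, features.n_voxels)) if collect_weights else None
    )
    rng = np.random.default_rng(seed)
    for b in range(n_perm):
        perm_labels = rng.permutation(labels)
        res = losocv(features, perm_labels, algorithm=algorithm, **cv_kwargs)
        for m in tracked:
            nulls[m][b] = res.metrics[m]
        if collect_weights:
            null_w[b] = weight_contribution(res.mean_weights)
    result = PermutationResult(
        observed={m: observed.metrics[m] for m in tracked},
        null_values=nulls,
        n_perm=n_perm,
        seed=seed,
        null_weights=null_w,
    )
    return result, observed


def permute_voxel_weights(
    observed_mean_weights: np.ndarray, null_weights: np.ndarray
) -> np.ndarray:
    """Per-voxel permutation p from contribution-statistic nulls.

    p(v) = #{replicates with |null statistic| >= |observed statistic|} /
    n_perm (ties count toward the numerator, so an all-zero voxel has
    p = 1).  Observed and null vectors must be on the same scale — pass
    both through :func:`weight_contribution` (as ``permute_performance``
    and ``build_discriminative_map`` do).
    """
    if null_weights is None:
        raise ValueError("no permuted weights were collected")
    obs = np.abs(np.asarray(observed_mean_weights))
    null = np.asarray(null_weights)
    if null.ndim != 2 or null.shape[1] != obs.shape[0]:
        raise ValueError(
            f"null weights shape {null.shape} inconsistent with {obs.shape[0]} voxels"
        )
    return np.mean(null >= obs[None, :], axis=0)


@dataclass
class ClusterROI:
    """A connected suprathreshold component of the discriminative map."""

    label: str
    voxels: np.ndarray  # (n, 3) grid coordinates
    peak: tuple[int, int, int]
    sign: str  # "positive" | "negative"
    mean_weight: float

    @property
    def size(self) -> int:
        return len(self.voxels)

    def mask(self, grid_shape: tuple[int, int, int]) -> np.ndarray:
        m = np.zeros(grid_shape, dtype=bool)
        m[tuple(self.voxels.T)] = True
        return m


def _structure(connectivity: int) -> np.ndarray:
    if connectivity == 6:
        return ndimage.generate_binary_structure(3, 1)
    if connectivity == 18:
        return ndimage.generate_binary_structure(3, 2)
    if connectivity == 26:
        return ndimage.generate_binary_structure(3, 3)
    raise ValueError(f"connectivity must be 6, 18 or 26; got {connectivity}")


def extract_clusters(
    voxel_p: np.ndarray,
    mean_weight: np.ndarray,
    alpha: float = 0.001,
    min_cluster: int = 30,
    connectivity: int = 26,
) -> list[ClusterROI]:
    """Threshold, label connected components, apply the extent cutoff.

    Voxels with p strictly below ``alpha`` are kept; components (under the
    chosen 3D connectivity) strictly larger than ``min_cluster`` voxels
    become ROIs, signed by their mean weight.  An empty list is a valid
    outcome.
    """
    voxel_p = np.asarray(voxel_p)
    mean_weight = np.asarray(mean_weight)
    if voxel_p.shape != mean_weight.shape:
        raise ValueError("voxel_p and mean_weight grids differ")
    supra = voxel_p < alpha
    labeled, n_comp = ndimage.label(supra, structure=_structure(connectivity))
    clusters: list[ClusterROI] = []
    for comp in range(1, n_comp + 1):
        coords = np.argwhere(labeled == comp)
        if len(coords) <= min_cluster:
            continue
        weights = mean_weight[tuple(coords.T)]
        peak = coords[np.argmax(np.abs(weights))]
        mw = float(weights.mean())
        clusters.append(
            ClusterROI(
                label=f"cluster{len(clusters) + 1:02d}",
                voxels=coords,
                peak=tuple(int(c) for c in peak),
                sign="positive" if mw >= 0 else "negative",
                mean_weight=mw,
            )
        )
    # largest first, ties broken by label order
    clusters.sort(key=lambda c: -c.size)
    for i, c in enumerate(clusters):
        c.label = f"cluster{i + 1:02d}"
    return clusters


def clusters_to_label_map(
    clusters: list[ClusterROI], grid_shape: tuple[int, int, int]
) -> np.ndarray:
    """Integer label volume: voxel value i belongs to clusters[i-1], 0 = none."""
    out = np.zeros(grid_shape, dtype=np.int32)
    for i, c in enumerate(clusters, start=1):
        out[tuple(c.voxels.T)] = i
    return out


def clusters_from_label_map(
    label_map: np.ndarray, mean_weight: np.ndarray | None = None
) -> list[ClusterROI]:
    """Rebuild cluster ROIs from an integer label volume."""
    label_map = np.asarray(label_map).astype(np.int32)
    if mean_weight is None:
        mean_weight = np.zeros(label_map.shape)
    clusters = []
    for i in range(1, int(label_map.max()) + 1):
        coords = np.argwhere(label_map == i)
        if len(coords) == 0:
            continue
        weights = mean_weight[tuple(coords.T)]
        peak = coords[np.argmax(np.abs(weights))]
        mw = float(weights.mean())
        clusters.append(
            ClusterROI(
                label=f"cluster{i:02d}",
                voxels=coords,
                peak=tuple(int(v) for v in peak),
                sign="positive" if mw >= 0 else "negative",
                mean_weight=mw,
            )
        )
    return clusters


@dataclass
class DiscriminativeMap:
    """Signed mean weight map with voxelwise permutation p and its ROIs."""

    mean_weight: np.ndarray
    voxel_p: np.ndarray
    clusters: list[ClusterROI]
    alpha: float
    min_cluster_voxels: int
    n_perm: int


def build_discriminative_map(
    features: FeatureMatrix,
    observed: CVResult,
    perm_result: PermutationResult,
    alpha: float = 0.001,
    min_cluster: int = 30,
    connectivity: int = 26,
) -> DiscriminativeMap:
    """Assemble the discriminative map from an observed run and its nulls.

    At reduced permutation counts, requesting an ``alpha`` below 1/n_perm
    is interpreted as the minimal attainable level (only voxels never
    reached by any permutation survive).
    """
    if features.grid_shape is None:
        raise ValueError("feature matrix lacks grid_shape")
    p_vec = permute_voxel_weights(
        weight_contribution(observed.mean_weights), perm_result.null_weights
    )
    alpha_eff = max(alpha, 0.5 / perm_result.n_perm)
    voxel_p = features_to_map(p_vec, features.voxel_index, features.grid_shape)
    # out-of-mask voxels must not enter clusters: give them p = 1
    in_mask = np.zeros(features.grid_shape, dtype=bool)
    in_mask[tuple(features.voxel_index.T)] = True
    voxel_p = np.where(in_mask, voxel_p, 1.0)
    mean_w = features_to_map(observed.mean_weights, features.voxel_index, features.grid_shape)
    clusters = extract_clusters(
        voxel_p, mean_w, alpha=alpha_eff, min_cluster=min_cluster, connectivity=connectivity
    )
    return DiscriminativeMap(
        mean_weight=mean_w,
        voxel_p=voxel_p,
        clusters=clusters,
        alpha=alpha_eff,
        min_cluster_voxels=min_cluster,
        n_perm=perm_result.n_perm,
    )
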