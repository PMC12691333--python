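"""Habitat partitioning: per-voxel (intensity, entropy) features, population-
level k-means, Calinski–Harabasz model selection, and habitat label maps.

The clustering operates on two features per tumor voxel: the voxel's HU value
and the Shannon entropy (base 2) of the gray-level histogram over its local
neighbourhood restricted to the tumor mask.  Voxels from all patients in the
(training) cohort are pooled, z-standardized with pooled statistics, and
clustered once at the population level; held-out patients are assigned to the
frozen centroids with the frozen standardization, never their own.

Habitat ids are canonicalized cohort-wide by ascending centroid intensity, so
"habitat 1" (Sub1) is always the lowest-attenuation subregion regardless of
the arbitrary cluster numbering a k-means run produces.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from sklearn.cluster import KMeans

from .io import TumorMask, VolumeImage, require_same_grid

__all__ = [
    "VoxelFeatureMap",
    "PooledVoxelFeatures",
    "ClusteringResult",
    "KSelection",
    "HabitatMap",
    "entropy_map",
    "pool_cohort_features",
    "kmeans_cluster",
    "calinski_harabasz",
    "select_k",
    "label_habitats",
    "assign_to_centroids",
    "cluster_cohort",
]


@dataclass
class VoxelFeatureMap:
    """Per-voxel (intensity, entropy) records for one patient's tumor.

    ``indices`` are the (z, y, x) coordinates of the masked voxels, in the
    fixed order shared by ``intensity``/``entropy``; ``small_neighborhood``
    flags voxels whose mask-restricted neighbourhood had fewer than 2 voxels
    (their entropy is defined as 0).
    """

    intensity: np.ndarray
    entropy: np.ndarray
    indices: tuple[np.ndarray, np.ndarray, np.ndarray]
    shape: tuple[int, int, int]
    n_bins: int
    small_neighborhood: np.ndarray

    def __len__(self) -> int:
        return len(self.intensity)

    @property
    def features(self) -> np.ndarray:
        """(n_voxels, 2) matrix: columns intensity, entropy."""
        return np.column_stack([self.intensity, self.entropy])


def _box_counts(indicator: np.ndarray, window: int, per_slice: bool) -> np.ndarray:
    """Box-sum of an indicator over (2*window+1)^d neighbourhoods."""
    size = 2 * window + 1
    sizes = (1, size, size) if per_slice else (size, size, size)
    kernel_n = int(np.prod(sizes))
    summed = ndimage.uniform_filter(
        indicator.astype(np.float64), size=sizes, mode="constant", cval=0.0
    ) * kernel_n
    return np.rint(summed)


def entropy_map(
    image: VolumeImage,
    mask: TumorMask,
    window: int = 1,
    n_bins: int = 32,
    eps: float = 1e-12,
    per_slice: bool = False,
) -> VoxelFeatureMap:
    """Local Shannon entropy of the gray-level histogram around each voxel.

    For each tumor voxel, intensities of the cubic neighbourhood of radius
    ``window`` *intersected with the mask* are histogrammed into ``n_bins``
    equal-width bins spanning the patient's masked HU range, and

        H = -sum_i p_i * log2(p_i + eps)

    with ``eps`` guarding the ``p = 0`` terms inside the log.  ``per_slice``
    restricts the neighbourhood to the axial plane (2D reading of
    slice-by-slice entropy); the default is the full 3D neighbourhood.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    if eps <= 0:
        raise ValueError("eps must be positive")
    require_same_grid(image, mask)

    inside = mask.labels > 0
    vals = image.values[inside]
    lo, hi = float(vals.min()), float(vals.max())
    if hi <= lo:
        levels = np.zeros(image.shape, dtype=np.int32)
        n_eff = 1
    else:
        edges = np.linspace(lo, hi, n_bins + 1)
        levels = np.clip(
            np.searchsorted(edges, image.values, side="right") - 1, 0, n_bins - 1
        ).astype(np.int32)
        n_eff = n_bins

    totals = _box_counts(inside, window, per_slice)
    ent = np.zeros(image.shape, dtype=np.float64)
    with np.errstate(divide="ignore", invalid="ignore"):
        for b in range(n_eff):
            counts = _box_counts(inside & (levels == b), window, per_slice)
            p = np.where(totals > 0, counts / np.maximum(totals, 1), 0.0)
            ent -= p * np.log2(p + eps)

    idx = np.nonzero(inside)
    small = totals[idx] < 2
    entropy = ent[idx]
    entropy[small] = 0.0
    entropy = np.maximum(entropy, 0.0)
    return VoxelFeatureMap(
        intensity=image.values[idx],
        entropy=entropy,
        indices=idx,
        shape=image.shape,
        n_bins=n_eff,
        small_neighborhood=small,
    )


@dataclass
class PooledVoxelFeatures:
    """Cohort-pooled, z-standardized voxel feature matrix.

    ``matrix`` is (total_voxels, 2); ``patient_index`` maps each row to its
    patient; ``mean``/``std`` are the pooled standardization parameters, kept
    so held-out patients can be standardized with *training* statistics.
    """

    matrix: np.ndarray
    patient_index: np.ndarray
    mean: np.ndarray
    std: np.ndarray

    def transform(self, fmap: VoxelFeatureMap) -> np.ndarray:
        """Standardize a new patient's features with the stored parameters."""
        return (fmap.features - self.mean) / self.std


def pool_cohort_features(maps: list[VoxelFeatureMap]) -> PooledVoxelFeatures:
    """Stack per-patient voxel features and z-standardize with pooled stats."""
    if not maps:
        raise ValueError("need at least one patient")
    raw = np.vstack([m.features for m in maps])
    patient_index = np.concatenate(
        [np.full(len(m), i, dtype=np.int32) for i, m in enumerate(maps)]
    )
    mean = raw.mean(axis=0)
    std = raw.std(axis=0)
    for name, s in zip(("intensity", "entropy"), std):
        if s < 1e-12:
            raise ValueError(f"pooled {name} column has zero variance")
    return PooledVoxelFeatures(
        matrix=(raw - mean) / std, patient_index=patient_index,
        mean=mean, std=std,
    )


@dataclass
class ClusteringResult:
    """One k-means fit on the pooled matrix (assignments are 1-based)."""

    centroids: np.ndarray
    assignment: np.ndarray
    inertia: float
    k: int
    ch: float = float("nan")


def kmeans_cluster(
    matrix: np.ndarray,
    k: int,
    seed: int = 0,
    n_init: int = 10,
    max_iter: int = 300,
    tol: float = 1e-4,
) -> ClusteringResult:
    """Euclidean k-means (Lloyd, k-means++ init, best of ``n_init`` restarts)."""
    matrix = np.asarray(matrix, dtype=np.float64)
    if k < 2:
        raise ValueError("k must be >= 2")
    if len(matrix) < k:
        raise ValueError(f"need at least k={k} rows, got {len(matrix)}")
    km = KMeans(
        n_clusters=k, n_init=n_init, max_iter=max_iter, tol=tol,
        random_state=seed, algorithm="lloyd",
    ).fit(matrix)
    result = ClusteringResult(
        centroids=km.cluster_centers_,
        assignment=km.labels_.astype(np.int32) + 1,
        inertia=float(km.inertia_),
        k=k,
    )
    if len(np.unique(result.assignment)) < 2:
        # all rows identical: zero within-dispersion sentinel
        result.ch = float("inf")
    else:
        result.ch = calinski_harabasz(matrix, result.assignment)
    return result


def calinski_harabasz(matrix: np.ndarray, assignment: np.ndarray) -> float:
    """Calinski–Harabasz index of a hard partition.

    CH = [B / (k - 1)] / [W / (n - k)] with B and W the traces of the
    between- and within-cluster scatter about the grand mean and centroids.
    A zero within-cluster dispersion returns ``inf`` (perfectly tight
    clusters, e.g. every point its own cluster).
    """
    matrix = np.asarray(matrix, dtype=np.float64)
    assignment = np.asarray(assignment)
    labels = np.unique(assignment)
    k, n = len(labels), len(matrix)
    if k < 2:
        raise ValueError("need at least 2 clusters")
    if n < k:
        raise ValueError("need at least as many points as clusters")
    grand = matrix.mean(axis=0)
    between = 0.0
    within = 0.0
    for lab in labels:
        pts = matrix[assignment == lab]
        c = pts.mean(axis=0)
        between += len(pts) * float(((c - grand) ** 2).sum())
        within += float(((pts - c) ** 2).sum())
    if within <= 0.0:
        return float("inf")
    return (between / (k - 1)) / (within / (n - k))


@dataclass
class KSelection:
    """CH-based habitat-count selection over a k range."""

    k_star: int
    ch_by_k: dict[int, float]
    results: dict[int, ClusteringResult] = field(repr=False, default_factory=dict)

    @property
    def best(self) -> ClusteringResult:
        return self.results[self.k_star]


def select_k(
    matrix: np.ndarray,
    k_range=range(2, 7),
    seed: int = 0,
    **kmeans_kwargs,
) -> KSelection:
    """Fit k-means for each k and pick the CH argmax (ties toward smaller k)."""
    ks = sorted(set(int(k) for k in k_range))
    if not ks or ks[0] < 2 or ks[-1] > 10:
        raise ValueError("k_range must lie within [2, 10]")
    ch_by_k: dict[int, float] = {}
    results: dict[int, ClusteringResult] = {}
    best_k, best_ch = None, -np.inf
    for k in ks:  # ascending, strict > : ties resolve to the smaller k
        res = kmeans_cluster(matrix, k, seed=seed, **kmeans_kwargs)
        ch_by_k[k] = res.ch
        results[k] = res
        if res.ch > best_ch:
            best_k, best_ch = k, res.ch
    assert best_k is not None
    return KSelection(k_star=best_k, ch_by_k=ch_by_k, results=results)


@dataclass
class HabitatMap:
    """Integer relabeling of one tumor: 0 background, 1..k habitats."""

    labels: np.ndarray
    k: int
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    direction: np.ndarray = field(default_factory=lambda: np.eye(3))

    def region_mask(self, habitat: int) -> TumorMask | None:
        """Binary mask of one habitat; None if absent in this patient."""
        region = self.labels == habitat
        if not region.any():
            return None
        return TumorMask(region.astype(np.uint8), self.spacing, self.origin,
                         self.direction)

    @property
    def present_habitats(self) -> list[int]:
        return [j for j in range(1, self.k + 1) if (self.labels == j).any()]


def _canonical_order(centroids: np.ndarray) -> np.ndarray:
    """Permutation of cluster ids sorted by ascending centroid intensity."""
    return np.argsort(centroids[:, 0], kind="stable")


def label_habitats(
    result: ClusteringResult,
    patient_index: np.ndarray,
    maps: list[VoxelFeatureMap],
    masks: list[TumorMask],
) -> list[HabitatMap]:
    """Scatter pooled cluster assignments back into per-patient label maps.

    Habitat ids are renumbered cohort-wide by ascending centroid (standardized)
    intensity, so the numbering is invariant to the arbitrary k-means label
    permutation.
    """
    order = _canonical_order(result.centroids)
    relabel = np.empty(result.k, dtype=np.int32)
    relabel[order] = np.arange(1, result.k + 1)
    canonical = relabel[result.assignment - 1]

    out: list[HabitatMap] = []
    for i, (fmap, mask) in enumerate(zip(maps, masks)):
        rows = patient_index == i
        labels = np.zeros(fmap.shape, dtype=np.int16)
        labels[fmap.indices] = canonical[rows]
        if int((labels > 0).sum()) != mask.n_voxels:
            raise ValueError(
                f"patient {i}: habitat foreground does not match the mask"
            )
        out.append(HabitatMap(labels=labels, k=result.k, spacing=mask.spacing,
                              origin=mask.origin, direction=mask.direction))
    return out


def assign_to_centroids(
    pooled: PooledVoxelFeatures,
    result: ClusteringResult,
    fmap: VoxelFeatureMap,
    mask: TumorMask,
) -> HabitatMap:
    """Assign a held-out patient's voxels to frozen training centroids.

    Standardization uses the stored *training* parameters; each voxel goes to
    its nearest centroid, then ids are canonicalized exactly as in
    :func:`label_habitats`.
    """
    x = pooled.transform(fmap)
    d = ((x[:, None, :] - result.centroids[None, :, :]) ** 2).sum(axis=2)
    raw = np.argmin(d, axis=1) + 1
    order = _canonical_order(result.centroids)
    relabel = np.empty(result.k, dtype=np.int32)
    relabel[order] = np.arange(1, result.k + 1)
    labels = np.zeros(fmap.shape, dtype=np.int16)
    labels[fmap.indices] = relabel[raw - 1]
    return HabitatMap(labels=labels, k=result.k, spacing=mask.spacing,
                      origin=mask.origin, direction=mask.direction)


def cluster_cohort(
    images: list[VolumeImage],
    masks: list[TumorMask],
    k_range=range(2, 7),
    seed: int = 0,
    window: int = 1,
    n_bins: int = 32,
    eps: float = 1e-12,
) -> tuple[KSelection, list[HabitatMap], PooledVoxelFeatures]:
    """End-to-end habitat partition of a cohort.

    Computes per-voxel features, pools and standardizes them, selects the
    habitat count by CH, and returns per-patient habitat maps.
    """
    fmaps = [
        entropy_map(img, msk, window=window, n_bins=n_bins, eps=eps)
        for img, msk in zip(images, masks)
    ]
    pooled = pool_cohort_features(fmaps)
    selection = select_k(pooled.matrix, k_range=k_range, seed=seed)
    habitat_maps = label_habitats(
        selection.best, pooled.patient_index, fmaps, masks
    )
    return selection, habitat_maps, pooled
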