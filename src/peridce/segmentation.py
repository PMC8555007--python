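"""Two-stage k-means tumour segmentation and reference-tissue segmentation.

The tumour workflow mirrors a semi-automatic 3D pipeline: the last
post-contrast volume of a cropped series is collapsed to a 2D maximum
intensity projection (MIP), a 2-cluster k-means on the MIP yields a coarse
enhancement mask, small 2D objects are discarded, the mask is propagated
through every slice and time point, and a 4-cluster k-means on the masked
first post-contrast volume followed by largest-3D-component retention gives
the final tumour mask.  Fibroglandular (FGT) and adipose reference tissues
are segmented from the pre-contrast volume of a healthy-breast crop; skin,
which shares the FGT intensity cluster, is stripped by binary erosion.

k-means operates on scalar voxel intensity with Lloyd iterations, k-means++
seeding and a centroid-shift stopping tolerance; clusters are relabelled so
that cluster 0 is the darkest.  All randomness derives from the configured
seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage
from skimage import morphology

from .errors import PeridceError, ValidationError
from .io_dce import VolumeMask

logger = logging.getLogger(__name__)

_MAX_ITER_DEFAULT = 100


@dataclass
class ClusterResult:
    """Outcome of a k-means run on an intensity lattice."""

    labels: np.ndarray          # integer lattice, same shape as input
    centroids: np.ndarray       # ascending mean intensity per cluster
    k: int
    tolerance: float
    seed: int
    n_iter: int = 0
    converged: bool = True
    sse: float = 0.0
    sse_history: np.ndarray = field(default_factory=lambda: np.empty(0))


@dataclass
class SegmentationConfig:
    """Tunable knobs of the segmentation stage.

    ``tolerance`` is the centroid-shift stopping threshold (0.0001 by
    default); ``min_object_area_2d`` removes specks from the clustered MIP;
    ``tumour_cluster_rule`` is ``"brightest"`` or an explicit list of cluster
    indices (the scripted equivalent of observer intervention);
    ``erosion_iterations`` strips skin from the FGT cluster.
    """

    k_initial: int = 2
    k_refine: int = 4
    tolerance: float = 1e-4
    seed: int = 0
    min_object_area_2d: int = 25
    tumour_cluster_rule: str | Sequence[int] = "brightest"
    erosion_iterations: int = 3
    fgt_k: int = 3
    fgt_cluster_rank: int = -1       # brightest of fgt_k by default
    adipose_cluster_rank: int = -2   # next-darker cluster (above air)
    connectivity_3d: int = 26
    connectivity_2d: int = 8
    max_iter: int = _MAX_ITER_DEFAULT
    n_init: int = 10

    def __post_init__(self) -> None:
        if self.k_initial < 2 or self.k_refine < 2 or self.fgt_k < 2:
            raise ValidationError("cluster counts must be >= 2")
        if self.tolerance <= 0:
            raise ValidationError("tolerance must be > 0")
        if self.min_object_area_2d < 0 or self.erosion_iterations < 0:
            raise ValidationError("thresholds must be >= 0")
        if self.connectivity_3d not in (6, 26) or self.connectivity_2d not in (4, 8):
            raise ValidationError("connectivity must be 6/26 (3D) or 4/8 (2D)")


# ---------------------------------------------------------------------------
# projection
# ---------------------------------------------------------------------------

def max_intensity_projection(volume: np.ndarray, axis: int = 0) -> np.ndarray:
    """Per-pixel maximum along one spatial axis of a 3D volume."""
    volume = np.asarray(volume)
    if volume.ndim != 3:
        raise ValidationError(f"MIP needs a 3D volume, got {volume.ndim}D")
    return volume.max(axis=axis)


# ---------------------------------------------------------------------------
# scalar k-means
# ---------------------------------------------------------------------------

def _kmeanspp_init(values: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    centers = np.empty(k)
    centers[0] = values[rng.integers(values.size)]
    d2 = (values - centers[0]) ** 2
    for j in range(1, k):
        total = d2.sum()
        if total <= 0:
            # remaining mass degenerate; fall back to distinct values
            centers[j] = rng.choice(np.unique(values))
        else:
            centers[j] = values[rng.choice(values.size, p=d2 / total)]
        d2 = np.minimum(d2, (values - centers[j]) ** 2)
    return centers


def _lloyd(values: np.ndarray, centers: np.ndarray, tolerance: float, max_iter: int):
    history = []
    labels = np.zeros(values.size, dtype=np.intp)
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        dist = np.abs(values[:, None] - centers[None, :])
        labels = np.argmin(dist, axis=1)
        history.append(float((dist[np.arange(values.size), labels] ** 2).sum()))
        new = centers.copy()
        for j in range(centers.size):
            sel = labels == j
            if sel.any():
                new[j] = values[sel].mean()
            else:  # re-seed an empty cluster at the farthest point
                new[j] = values[np.argmax(np.min(np.abs(values[:, None] - new[None, :]), axis=1))]
        shift = np.max(np.abs(new - centers))
        centers = new
        if shift < tolerance:
            converged = True
            break
    dist = np.abs(values[:, None] - centers[None, :])
    labels = np.argmin(dist, axis=1)
    sse = float((dist[np.arange(values.size), labels] ** 2).sum())
    history.append(sse)
    return labels, centers, n_iter, converged, np.array(history)


def kmeans(
    values: np.ndarray,
    k: int,
    tolerance: float = 1e-4,
    seed: int = 0,
    max_iter: int = _MAX_ITER_DEFAULT,
    n_init: int = 10,
) -> ClusterResult:
    """Cluster scalar intensities into *k* groups by Lloyd's algorithm.

    Runs ``n_init`` k-means++ starts (all derived from ``seed``) and keeps
    the lowest within-cluster sum of squares.  Clusters are relabelled in
    ascending centroid order, so label 0 is always the darkest tissue.
    """
    arr = np.asarray(values, dtype=float)
    flat = arr.ravel()
    if np.unique(flat).size < k:
        raise ValidationError(f"need at least {k} distinct values for k={k}")
    rng = np.random.default_rng(seed)
    best = None
    for _ in range(max(1, n_init)):
        init = _kmeanspp_init(flat, k, rng)
        out = _lloyd(flat, init, tolerance, max_iter)
        if best is None or out[4][-1] < best[4][-1] - 1e-12:
            best = out
    labels, centers, n_iter, converged, history = best
    if not converged:
        logger.warning("k-means did not converge in %d iterations (shift tolerance %g)",
                       max_iter, tolerance)
    order = np.argsort(centers, kind="stable")
    remap = np.empty_like(order)
    remap[order] = np.arange(k)
    return ClusterResult(
        labels=remap[labels].reshape(arr.shape),
        centroids=centers[order],
        k=k,
        tolerance=tolerance,
        seed=seed,
        n_iter=n_iter,
        converged=converged,
        sse=float(history[-1]),
        sse_history=history,
    )


# ---------------------------------------------------------------------------
# MIP mask stage
# ---------------------------------------------------------------------------

def binarize_enhanced(cluster: ClusterResult) -> np.ndarray:
    """Boolean mask of the brighter cluster of a 2-cluster result."""
    if cluster.k != 2:
        raise ValidationError("binarize_enhanced expects a k=2 clustering")
    return cluster.labels == 1


def remove_small_objects_2d(mask: np.ndarray, min_area: int, connectivity: int = 8) -> np.ndarray:
    """Drop 2D connected components smaller than ``min_area`` pixels."""
    mask = np.asarray(mask, dtype=bool)
    if mask.ndim != 2:
        raise ValidationError("expected a 2D mask")
    if min_area <= 0:
        return mask.copy()
    conn = 2 if connectivity == 8 else 1
    # drop components with area < min_area (i.e. <= min_area - 1)
    return morphology.remove_small_objects(mask, max_size=min_area - 1, connectivity=conn)


def apply_mip_mask(volumes: Sequence[np.ndarray], mip_mask: np.ndarray) -> list[np.ndarray]:
    """Zero out voxels outside the MIP mask, identically at every time point.

    The mask is a 2D (y, x) stencil: a voxel ``(z, y, x)`` survives iff
    ``mip_mask[y, x]`` — projecting the coarse enhancement footprint through
    the whole stack.
    """
    mip_mask = np.asarray(mip_mask, dtype=bool)
    out = []
    for vol in volumes:
        vol = np.asarray(vol)
        if vol.shape[1:] != mip_mask.shape:
            raise ValidationError(
                f"MIP mask shape {mip_mask.shape} does not match volume (y,x) {vol.shape[1:]}"
            )
        out.append(vol * mip_mask[None, :, :])
    return out


# ---------------------------------------------------------------------------
# 3D refinement
# ---------------------------------------------------------------------------

def _structure_3d(connectivity: int) -> np.ndarray:
    return ndimage.generate_binary_structure(3, 1 if connectivity == 6 else 3)


def largest_component_3d(mask: VolumeMask | np.ndarray, connectivity: int = 26) -> VolumeMask:
    """Keep only the largest 3D connected component.

    Ties are broken in favour of the component containing the
    lexicographically smallest ``(z, y, x)`` voxel.
    """
    grid = mask.grid if isinstance(mask, VolumeMask) else np.asarray(mask, dtype=bool)
    if not grid.any():
        raise PeridceError("largest_component_3d: mask is empty")
    labels, n = ndimage.label(grid, structure=_structure_3d(connectivity))
    sizes = np.bincount(labels.ravel())[1:]
    best_size = sizes.max()
    tied = np.flatnonzero(sizes == best_size) + 1
    if tied.size == 1:
        keep = tied[0]
    else:
        flat = labels.ravel()
        # first occurrence in C order == lexicographically smallest (z,y,x)
        keep = min(tied, key=lambda lab: np.argmax(flat == lab))
    spacing = mask.spacing if isinstance(mask, VolumeMask) else (1.0, 1.0, 1.0)
    return VolumeMask(
        labels == keep,
        label=mask.label if isinstance(mask, VolumeMask) else "largest_component",
        spacing=spacing,
        provenance={"op": "largest_component_3d", "connectivity": connectivity,
                    "n_components": int(n), "component_size": int(best_size)},
    )


def refine_tumour(
    masked_volume: np.ndarray,
    config: SegmentationConfig,
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> VolumeMask:
    """4-cluster k-means on the masked first post-contrast volume.

    Zeroed (masked-out) voxels are excluded from clustering.  The retained
    clusters follow ``config.tumour_cluster_rule``: the single
    brightest-centroid cluster by default, or an explicit index list.  The
    largest 3D connected component of the retained voxels is the tumour.
    """
    vol = np.asarray(masked_volume, dtype=float)
    if vol.ndim != 3:
        raise ValidationError("refine_tumour expects a 3D volume")
    inside = vol > 0
    if not inside.any():
        raise PeridceError("refine_tumour: masked volume is empty")
    result = kmeans(vol[inside], config.k_refine, tolerance=config.tolerance,
                    seed=config.seed, max_iter=config.max_iter, n_init=config.n_init)
    if config.tumour_cluster_rule == "brightest":
        keep_clusters = [config.k_refine - 1]
    else:
        keep_clusters = list(config.tumour_cluster_rule)
    selected = np.isin(result.labels, keep_clusters)
    grid = np.zeros(vol.shape, dtype=bool)
    grid[inside] = selected
    if not grid.any():
        raise PeridceError("no tumour cluster: selection empty after cluster removal")
    out = largest_component_3d(VolumeMask(grid, "tumour", spacing), config.connectivity_3d)
    out.provenance.update({
        "op": "refine_tumour",
        "k": config.k_refine,
        "centroids": result.centroids.tolist(),
        "clusters_kept": keep_clusters,
        "seed": config.seed,
    })
    return out


def segment_tumour(
    volumes: Sequence[np.ndarray],
    config: SegmentationConfig,
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
    pre_contrast_index: int = 0,
) -> tuple[VolumeMask, np.ndarray]:
    """Full tumour chain on a cropped, deinterleaved series.

    MIP of the last post-contrast volume -> 2-means -> brighter cluster ->
    small-object removal -> mask propagation -> 4-means refinement on the
    first post-contrast volume -> largest 3D object.  Returns the tumour mask
    and the edited 2D MIP mask.
    """
    if len(volumes) < 2:
        raise ValidationError("need a pre-contrast and at least one post-contrast volume")
    mip = max_intensity_projection(np.asarray(volumes[-1]), axis=0)
    coarse = kmeans(mip, config.k_initial, tolerance=config.tolerance,
                    seed=config.seed, max_iter=config.max_iter, n_init=config.n_init)
    mip_mask = binarize_enhanced(coarse)
    mip_mask = remove_small_objects_2d(mip_mask, config.min_object_area_2d,
                                       config.connectivity_2d)
    if not mip_mask.any():
        raise PeridceError("MIP mask empty after small-object removal")
    masked = apply_mip_mask(volumes, mip_mask)
    first_post = masked[pre_contrast_index + 1]
    tumour = refine_tumour(first_post, config, spacing)
    tumour.provenance["mip_centroids"] = coarse.centroids.tolist()
    return tumour, mip_mask


# ---------------------------------------------------------------------------
# reference tissues
# ---------------------------------------------------------------------------

def _cluster_rank_mask(volume: np.ndarray, k: int, rank: int, config: SegmentationConfig) -> np.ndarray:
    result = kmeans(volume, k, tolerance=config.tolerance, seed=config.seed,
                    max_iter=config.max_iter, n_init=config.n_init)
    return result.labels == (rank % k)


def segment_fgt(
    pre_contrast_volume: np.ndarray,
    config: SegmentationConfig,
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> VolumeMask:
    """Fibroglandular tissue from the pre-contrast healthy-breast crop.

    Skin and FGT share an intensity cluster; the skin rind is removed by
    eroding the clustered volume from the outside
    (``config.erosion_iterations`` steps of the unit structuring element).
    """
    vol = np.asarray(pre_contrast_volume, dtype=float)
    if vol.ndim != 3:
        raise ValidationError("segment_fgt expects a 3D volume")
    grid = _cluster_rank_mask(vol, config.fgt_k, config.fgt_cluster_rank, config)
    if config.erosion_iterations > 0:
        grid = ndimage.binary_erosion(
            grid, structure=_structure_3d(6), iterations=config.erosion_iterations
        )
    if not grid.any():
        raise PeridceError("segment_fgt: mask empty after erosion")
    return VolumeMask(grid, "fgt", spacing, provenance={
        "op": "segment_fgt", "k": config.fgt_k,
        "cluster_rank": config.fgt_cluster_rank % config.fgt_k,
        "erosion_iterations": config.erosion_iterations, "seed": config.seed,
    })


def segment_adipose(
    pre_contrast_volume: np.ndarray,
    config: SegmentationConfig,
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> VolumeMask:
    """Adipose tissue: same clustering as FGT, different rank, no erosion."""
    vol = np.asarray(pre_contrast_volume, dtype=float)
    if vol.ndim != 3:
        raise ValidationError("segment_adipose expects a 3D volume")
    grid = _cluster_rank_mask(vol, config.fgt_k, config.adipose_cluster_rank, config)
    if not grid.any():
        raise PeridceError("segment_adipose: empty mask")
    return VolumeMask(grid, "adipose", spacing, provenance={
        "op": "segment_adipose", "k": config.fgt_k,
        "cluster_rank": config.adipose_cluster_rank % config.fgt_k,
        "seed": config.seed,
    })
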