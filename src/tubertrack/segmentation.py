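"""The eight-step virtual-excavation segmentation pipeline.

The working hypothesis is textural: granular soil is spatially
inhomogeneous while tuber tissue is homogeneous, so a *local variance*
map separates them where a plain absorption threshold cannot.  The
stages, applied to a normalized volume:

1. 3D median filter (noise suppression),
2. Gaussian-windowed local variance ``V = G_lam * I^2 - (G_lam * I)^2``,
3. binarization: low variance AND absorption above an air floor,
4. binary erosion with a ball element (disconnects tangent stolons),
5. 26-connectivity (chessboard-metric) component labeling,
6. per-label constrained dilation restoring the original object size,
7. minimum-volume filter on the restored objects.

One :class:`SegmentationParams` instance is meant to be frozen per
experiment and applied unchanged to every volume of every pot and
condition.  The variance threshold, if left unset, is calibrated once as
a low quantile of the variance distribution inside the pot of the first
volume and then frozen (see :func:`resolve_params`).

Both the variance window and the erosion shrink objects; the dilation
radius therefore defaults to the erosion radius plus about twice the
variance window scale, which restores the original size to within about
a voxel (see docs/methods.md for the derivation).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage as ndi

from .grids import LabelGrid, VoxelGrid

log = logging.getLogger(__name__)

__all__ = [
    "SegmentationParams",
    "median_filter_3d",
    "local_variance",
    "binarize",
    "erode",
    "dilate",
    "label_components",
    "dilate_labels",
    "estimate_variance_threshold",
    "resolve_params",
    "segment_volume",
]


@dataclass(frozen=True)
class SegmentationParams:
    """One parameter set, applied unchanged to every volume of an experiment.

    Attributes
    ----------
    median_radius_vox
        Radius of the cubic median window; the filter spans (2r+1)^3 voxels.
    lambda_mm
        Scale of the Gaussian local-variance window, in mm.
    variance_threshold
        Foreground = variance strictly below this.  ``None`` means
        "calibrate on the first volume" (see :func:`resolve_params`).
    variance_quantile
        Quantile of the in-pot variance distribution used for calibration.
    absorption_floor
        Voxels at or below this normalized absorption are background (air
        is homogeneous too and must be excluded explicitly).
    erosion_radius_vox / dilation_radius_vox
        Structuring element radii.  ``dilation_radius_vox=None``
        auto-selects ``erosion + round(2.2 * lambda/voxel)`` so that both
        the variance window's edge loss and the erosion are reversed
        (constant calibrated on analytic sphere phantoms; see
        docs/methods.md).
    min_object_volume_mm3
        Objects smaller than this after size restoration are dropped.
    """

    median_radius_vox: int = 1
    lambda_mm: float = 0.4
    variance_threshold: float | None = None
    variance_quantile: float = 0.25
    absorption_floor: float = 0.3
    erosion_radius_vox: int = 4
    dilation_radius_vox: int | None = None
    min_object_volume_mm3: float = 5.0

    def __post_init__(self):
        if self.median_radius_vox < 1:
            raise ValueError("median_radius_vox must be >= 1")
        if self.lambda_mm <= 0:
            raise ValueError("lambda_mm must be positive")
        if self.erosion_radius_vox < 1:
            raise ValueError("erosion_radius_vox must be >= 1")
        if self.dilation_radius_vox is not None and self.dilation_radius_vox < 1:
            raise ValueError("dilation_radius_vox must be >= 1")

    def dilation_radius_for(self, voxel_size_mm: float) -> int:
        if self.dilation_radius_vox is not None:
            return self.dilation_radius_vox
        sigma_vox = self.lambda_mm / voxel_size_mm
        return self.erosion_radius_vox + max(1, int(round(2.2 * sigma_vox)))


def ball(radius: int) -> np.ndarray:
    """Digital Euclidean ball structuring element (voxels with |offset| <= radius)."""
    r = int(radius)
    zz, yy, xx = np.mgrid[-r:r + 1, -r:r + 1, -r:r + 1]
    return (zz * zz + yy * yy + xx * xx) <= r * r


def median_filter_3d(grid: VoxelGrid, radius_vox: int) -> VoxelGrid:
    """Cubic (2r+1)^3 median filter with reflective edge handling."""
    if radius_vox < 1:
        raise ValueError("radius_vox must be >= 1")
    size = 2 * int(radius_vox) + 1
    return grid.with_data(ndi.median_filter(grid.data, size=size, mode="reflect"))


def local_variance(grid: VoxelGrid, lambda_mm: float) -> VoxelGrid:
    """Gaussian-windowed local variance ``V = G_lam * I^2 - (G_lam * I)^2``.

    ``lambda_mm`` is the isotropic Gaussian scale in mm, converted to a
    voxel-space sigma.  Negative round-off values are clamped to 0.
    """
    sigma_vox = float(lambda_mm) / grid.voxel_size_mm
    if sigma_vox < 0.5:
        raise ValueError(
            f"window unresolvable: lambda {lambda_mm} mm is below half a voxel "
            f"({grid.voxel_size_mm} mm voxels)")
    # center the data before convolving: E[(I-c)^2] - E[I-c]^2 is the same
    # variance but without catastrophic cancellation of large means
    data = grid.data.astype(np.float64, copy=False)
    centered = data - data.mean()
    m1 = ndi.gaussian_filter(centered, sigma_vox, mode="reflect")
    m2 = ndi.gaussian_filter(centered * centered, sigma_vox, mode="reflect")
    var = m2 - m1 * m1
    np.maximum(var, 0.0, out=var)
    return grid.with_data(var)


def binarize(
    variance_grid: VoxelGrid,
    intensity_grid: VoxelGrid,
    variance_threshold: float,
    absorption_floor: float,
) -> np.ndarray:
    """Foreground = homogeneous (low variance) and denser than air."""
    if not (np.isfinite(variance_threshold) and np.isfinite(absorption_floor)):
        raise ValueError("thresholds must be finite")
    if variance_grid.shape != intensity_grid.shape:
        raise ValueError("variance and intensity grids must be congruent")
    return (variance_grid.data < variance_threshold) & (intensity_grid.data > absorption_floor)


def erode(mask: np.ndarray, radius_vox: int) -> np.ndarray:
    """Binary erosion with a ball structuring element."""
    if radius_vox < 1:
        raise ValueError("radius_vox must be >= 1")
    return ndi.binary_erosion(mask, structure=ball(radius_vox))


def dilate(mask: np.ndarray, radius_vox: int) -> np.ndarray:
    """Binary dilation with a ball structuring element."""
    if radius_vox < 1:
        raise ValueError("radius_vox must be >= 1")
    return ndi.binary_dilation(mask, structure=ball(radius_vox))


_CHESSBOARD = np.ones((3, 3, 3), dtype=bool)  # 26-neighborhood adjacency


def label_components(
    mask: np.ndarray,
    voxel_size_mm: float = 1.0,
    min_object_volume_mm3: float = 0.0,
    **grid_kwargs,
) -> LabelGrid:
    """Connected components under the chessboard (26-neighborhood) metric.

    Components are relabeled densely 1..N by decreasing voxel count
    (ties keep raster-scan order), so label 1 is always the largest
    object.  Components below ``min_object_volume_mm3`` are removed.
    """
    raw, n = ndi.label(mask, structure=_CHESSBOARD)
    if n == 0:
        return LabelGrid(raw.astype(np.int32), voxel_size_mm, **grid_kwargs)
    counts = np.bincount(raw.ravel(), minlength=n + 1)
    min_voxels = min_object_volume_mm3 / float(voxel_size_mm) ** 3
    order = sorted(range(1, n + 1), key=lambda lab: (-counts[lab], lab))
    remap = np.zeros(n + 1, dtype=np.int32)
    nxt = 1
    for lab in order:
        if counts[lab] >= min_voxels and counts[lab] > 0:
            remap[lab] = nxt
            nxt += 1
    return LabelGrid(remap[raw], voxel_size_mm, **grid_kwargs)


def _chamfer_schedule(rounds: int) -> list[bool]:
    """Which growth rounds use the 26-neighborhood (cube) vs the 6-neighborhood.

    Pure cross rounds grow an octahedron, pure cube rounds a cube; mixing
    them ~0.366 cube per round makes the grown region approximate a
    Euclidean ball (a standard chamfer construction).
    """
    n_cube = int(round(0.366 * rounds))
    marks = {int(round((i + 0.5) * rounds / max(n_cube, 1))) for i in range(n_cube)}
    return [k in marks for k in range(rounds)]


_CROSS = ndi.generate_binary_structure(3, 1)


def dilate_labels(labels: LabelGrid, radius_vox: int) -> LabelGrid:
    """Per-label constrained dilation: labels grow into background only.

    All labels grow simultaneously, one voxel shell per round, along a
    chamfer (cross/cube) schedule approximating a Euclidean ball of the
    given radius.  A contested background voxel goes to the lowest label
    id reaching it in that round; existing labels are never overwritten,
    so touching objects cannot merge.  Cost is independent of the number
    of labels.
    """
    if radius_vox < 1:
        raise ValueError("radius_vox must be >= 1")
    big = np.iinfo(np.int32).max
    lab = labels.labels.astype(np.int32, copy=False)
    work = np.where(lab > 0, lab, big)
    for use_cube in _chamfer_schedule(int(radius_vox)):
        if use_cube:
            mn = ndi.minimum_filter(work, size=3, mode="constant", cval=big)
        else:
            mn = ndi.minimum_filter(work, footprint=_CROSS, mode="constant", cval=big)
        np.copyto(work, mn, where=(work == big))
    out = np.where(work == big, 0, work)
    return LabelGrid(out, labels.voxel_size_mm, origin_mm=labels.origin_mm,
                     timepoint_days=labels.timepoint_days, pot_id=labels.pot_id)


def estimate_variance_threshold(grid: VoxelGrid, params: SegmentationParams) -> float:
    """Calibrate the variance threshold on one volume.

    Takes a low quantile of the local-variance distribution inside the pot
    (voxels above the absorption floor): tubers and other homogeneous
    bodies populate the low tail, granular soil the bulk.
    """
    med = median_filter_3d(grid, params.median_radius_vox)
    var = local_variance(med, params.lambda_mm)
    inside = med.data > params.absorption_floor
    if not inside.any():
        raise ValueError("no voxels above the absorption floor; cannot calibrate threshold")
    return float(np.quantile(var.data[inside], params.variance_quantile))


def resolve_params(grid: VoxelGrid, params: SegmentationParams) -> SegmentationParams:
    """Freeze data-dependent defaults against the experiment's first volume."""
    resolved = params
    if params.variance_threshold is None:
        tau = estimate_variance_threshold(grid, params)
        resolved = replace(resolved, variance_threshold=tau)
        log.info("variance threshold calibrated on pot=%s t=%.3g: %.4g",
                 grid.pot_id, grid.timepoint_days, tau)
    if params.dilation_radius_vox is None:
        resolved = replace(resolved, dilation_radius_vox=params.dilation_radius_for(grid.voxel_size_mm))
    return resolved


def segment_volume(grid: VoxelGrid, params: SegmentationParams) -> LabelGrid:
    """Run the full stage composition on one normalized volume."""
    if not grid.normalized:
        raise ValueError("segment_volume requires a normalized volume")
    params = resolve_params(grid, params)

    med = median_filter_3d(grid, params.median_radius_vox)
    var = local_variance(med, params.lambda_mm)
    mask = binarize(var, med, params.variance_threshold, params.absorption_floor)
    n_fg = int(mask.sum())
    eroded = erode(mask, params.erosion_radius_vox)
    labelled = label_components(
        eroded, grid.voxel_size_mm,
        origin_mm=grid.origin_mm, timepoint_days=grid.timepoint_days, pot_id=grid.pot_id)
    n_components = len(labelled.label_ids)
    restored = dilate_labels(labelled, params.dilation_radius_for(grid.voxel_size_mm))

    # minimum-volume filter at restored (original) object size
    counts = np.bincount(restored.labels.ravel())
    min_voxels = params.min_object_volume_mm3 / grid.voxel_volume_mm3
    keep = [lab for lab in range(1, counts.size) if counts[lab] >= min_voxels]
    remap = np.zeros(counts.size, dtype=np.int32)
    for new, lab in enumerate(sorted(keep, key=lambda l: (-counts[l], l)), start=1):
        remap[lab] = new
    final = LabelGrid(remap[restored.labels], grid.voxel_size_mm, origin_mm=grid.origin_mm,
                      timepoint_days=grid.timepoint_days, pot_id=grid.pot_id)
    log.info("segment pot=%s t=%.3g: foreground %d vox -> %d components -> %d objects >= %.3g mm3",
             grid.pot_id, grid.timepoint_days, n_fg, n_components, len(keep),
             params.min_object_volume_mm3)
    return final
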