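"""Core volumetric containers shared by all pipeline stages.

A reconstructed CT volume is a 3D scalar field of linear absorption
coefficients on an isotropic voxel lattice.  Axis order is fixed as
``(z, y, x)`` with 0-based indices; the physical coordinate of voxel
``(i, j, k)`` is ``origin_mm + (index + 0.5) * voxel_size_mm`` (voxel
centers sit at half-integer offsets).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["VoxelGrid", "LabelGrid"]


def _as_origin(origin) -> np.ndarray:
    arr = np.asarray(origin, dtype=float)
    if arr.shape != (3,):
        raise ValueError(f"origin_mm must be a 3-vector, got shape {arr.shape}")
    return arr


@dataclass
class VoxelGrid:
    """A 3D scalar field of reconstructed linear absorption coefficients.

    Parameters
    ----------
    data
        3D array, axis order (z, y, x).
    voxel_size_mm
        Isotropic voxel edge length in mm (> 0).
    origin_mm
        Physical position of the grid corner (mm); voxel centers are at
        ``origin_mm + (index + 0.5) * voxel_size_mm``.
    normalized
        Whether intensities have been rescaled to the common air/water
        ladder (air = 0, water-like tissue = 1).
    timepoint_days
        Acquisition time in days since planting (>= 0).
    pot_id
        Identifier of the pot this volume belongs to.
    """

    data: np.ndarray
    voxel_size_mm: float
    origin_mm: np.ndarray = field(default_factory=lambda: np.zeros(3))
    normalized: bool = False
    timepoint_days: float = 0.0
    pot_id: str = ""

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3 or min(self.data.shape) < 1:
            raise ValueError(f"data must be 3D with all extents >= 1, got shape {self.data.shape}")
        if not np.isfinite(self.voxel_size_mm) or self.voxel_size_mm <= 0:
            raise ValueError(f"voxel_size_mm must be positive, got {self.voxel_size_mm}")
        if self.timepoint_days < 0:
            raise ValueError(f"timepoint_days must be non-negative, got {self.timepoint_days}")
        self.origin_mm = _as_origin(self.origin_mm)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(self.voxel_size_mm) ** 3

    def voxel_centers_mm(self, indices: np.ndarray) -> np.ndarray:
        """Physical coordinates (mm) of voxel indices, shape (n, 3), order (z, y, x)."""
        idx = np.atleast_2d(np.asarray(indices, dtype=float))
        return self.origin_mm + (idx + 0.5) * self.voxel_size_mm

    def with_data(self, data: np.ndarray, *, normalized: bool | None = None) -> "VoxelGrid":
        """A copy of this grid carrying new voxel data (same geometry/metadata)."""
        kwargs = {"data": data}
        if normalized is not None:
            kwargs["normalized"] = normalized
        return replace(self, **kwargs)


@dataclass
class LabelGrid:
    """Integer object labels sharing a :class:`VoxelGrid`'s geometry; 0 = background."""

    labels: np.ndarray
    voxel_size_mm: float
    origin_mm: np.ndarray = field(default_factory=lambda: np.zeros(3))
    timepoint_days: float = 0.0
    pot_id: str = ""

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("labels must be 3D")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("labels must be an integer array")
        if self.voxel_size_mm <= 0:
            raise ValueError("voxel_size_mm must be positive")
        self.origin_mm = _as_origin(self.origin_mm)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(self.voxel_size_mm) ** 3

    @property
    def label_ids(self) -> np.ndarray:
        ids = np.unique(self.labels)
        return ids[ids != 0]

    def same_geometry_as(self, other) -> bool:
        return (
            self.shape == other.shape
            and np.isclose(self.voxel_size_mm, other.voxel_size_mm)
            and np.allclose(self.origin_mm, other.origin_mm)
        )
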