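"""Per-object features and the three false-positive rejection rules.

Each labeled object yields an :class:`ObjectRecord` with volume, mean
absorption, intensity-weighted centroid ("center of mass"), principal
semi-axis lengths from the second-moment tensor, and the aspect ratio
(longest/shortest axis).  Three rules then demote false positives:

* absorption — mean absorption outside a water-like band marks dense
  mineral bodies (stones, clay) whose absorption tracks their density;
* aspect — elongated objects (disconnected stolon fragments) are far
  from spherical;
* growth — a tuber has to grow over time; homogeneous objects whose
  volume never increases across the series are rejected, with an
  optional exemption window for a declared stress period, during which
  growth arrest is biology rather than a segmentation error.

Classification only ever moves records out of "candidate"; a rejected
record is never resurrected.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .grids import LabelGrid, VoxelGrid

log = logging.getLogger(__name__)

__all__ = [
    "CLASS_CANDIDATE", "CLASS_TUBER", "CLASS_STONE", "CLASS_STOLON", "CLASS_NONGROWING",
    "ObjectRecord",
    "extract_features",
    "classify_absorption",
    "classify_aspect",
    "classify_growth",
    "records_to_dataframe",
]

CLASS_CANDIDATE = "candidate"
CLASS_TUBER = "tuber"
CLASS_STONE = "rejected_stone"
CLASS_STOLON = "rejected_stolon"
CLASS_NONGROWING = "rejected_nongrowing"


@dataclass
class ObjectRecord:
    """Features of one connected object at one timepoint."""

    pot_id: str
    timepoint_days: float
    label: int
    volume_mm3: float
    mean_absorption: float
    centroid_mm: np.ndarray              # (z, y, x), physical coordinates
    axis_lengths_mm: np.ndarray          # principal semi-axes, descending
    aspect_ratio: float
    object_class: str = CLASS_CANDIDATE
    voxel_count: int = 0
    fresh_weight_g: float | None = None

    def __post_init__(self):
        self.centroid_mm = np.asarray(self.centroid_mm, dtype=float)
        self.axis_lengths_mm = np.asarray(self.axis_lengths_mm, dtype=float)
        if self.volume_mm3 <= 0:
            raise ValueError("volume_mm3 must be positive")
        ax = self.axis_lengths_mm
        if np.any(ax <= 0) or np.any(np.diff(ax) > 1e-12):
            raise ValueError(f"axis lengths must be positive and descending, got {ax}")
        if self.aspect_ratio < 1 - 1e-9:
            raise ValueError("aspect_ratio must be >= 1")


def _principal_semi_axes(coords_mm: np.ndarray, voxel_size_mm: float) -> np.ndarray:
    """Semi-axes of the uniform ellipsoid with the voxel cloud's second moments.

    For a uniform solid ellipsoid the positional variance along principal
    axis ``a`` is ``a^2 / 5``, so ``a = sqrt(5 * eigenvalue)``.  Each voxel
    contributes its own cubic spread (edge^2/12 per axis), which keeps the
    result positive for single-voxel objects.
    """
    centered = coords_mm - coords_mm.mean(axis=0)
    cov = centered.T @ centered / coords_mm.shape[0]
    cov += np.eye(3) * (voxel_size_mm ** 2 / 12.0)
    eigvals = np.linalg.eigvalsh(cov)  # ascending
    return np.sqrt(5.0 * np.clip(eigvals[::-1], 0.0, None))


def extract_features(grid: VoxelGrid, labels: LabelGrid) -> list[ObjectRecord]:
    """One record per label; empty label set gives an empty list."""
    if grid.shape != labels.shape:
        raise ValueError("intensity and label grids must be congruent")
    lab = labels.labels
    ids = labels.label_ids
    if ids.size == 0:
        return []
    records = []
    objects = ndi.find_objects(lab)
    voxvol = grid.voxel_volume_mm3
    for i in ids:
        sl = objects[int(i) - 1]
        mask = lab[sl] == i
        intensities = np.asarray(grid.data[sl][mask], dtype=float)
        count = int(mask.sum())
        idx = np.argwhere(mask) + np.array([s.start for s in sl])
        coords = grid.origin_mm + (idx + 0.5) * grid.voxel_size_mm
        weights = np.clip(intensities, 0.0, None)
        wsum = weights.sum()
        centroid = (coords * weights[:, None]).sum(axis=0) / wsum if wsum > 0 else coords.mean(axis=0)
        axes = _principal_semi_axes(coords, grid.voxel_size_mm)
        records.append(ObjectRecord(
            pot_id=grid.pot_id,
            timepoint_days=grid.timepoint_days,
            label=int(i),
            volume_mm3=count * voxvol,
            mean_absorption=float(intensities.mean()),
            centroid_mm=centroid,
            axis_lengths_mm=axes,
            aspect_ratio=float(axes[0] / axes[-1]),
            voxel_count=count,
        ))
    return records


def classify_absorption(
    records: list[ObjectRecord], absorption_band: tuple[float, float] = (0.8, 1.3)
) -> list[ObjectRecord]:
    """Reject candidates whose mean absorption leaves the water-like band (closed interval)."""
    low, high = absorption_band
    if not low < high:
        raise ValueError("absorption band must satisfy low < high")
    for rec in records:
        if rec.object_class == CLASS_CANDIDATE and not (low <= rec.mean_absorption <= high):
            rec.object_class = CLASS_STONE
    return records


def classify_aspect(records: list[ObjectRecord], max_aspect: float = 3.0) -> list[ObjectRecord]:
    """Reject candidates much more elongated than a sphere."""
    if max_aspect <= 1:
        raise ValueError("max_aspect must exceed 1")
    for rec in records:
        if rec.object_class == CLASS_CANDIDATE and rec.aspect_ratio > max_aspect:
            rec.object_class = CLASS_STOLON
    return records


def classify_growth(
    tracks,
    min_timepoints: int = 3,
    min_relative_growth: float = 0.05,
    stress_window: tuple[float, float] | None = None,
):
    """Apply the "a tuber has to grow over time" rule after the series ends.

    A track is kept (class "tuber") if its volume increases by at least
    ``min_relative_growth`` over some run of ``min_timepoints``
    consecutive usable observations; otherwise it is rejected as
    non-growing.  Observations inside a declared ``stress_window`` are
    exempt from the requirement: runs simply span the window, so a tuber
    that grew before or after a stress-induced arrest still qualifies.
    Tracks with fewer usable observations than ``min_timepoints`` cannot
    demonstrate growth and are rejected.
    """
    if min_timepoints < 2:
        raise ValueError("min_timepoints must be >= 2")
    for track in tracks:
        if track.status != CLASS_CANDIDATE:
            continue
        obs = [(r.timepoint_days, r.volume_mm3) for r in track.records]
        if stress_window is not None:
            a, b = stress_window
            usable = [(t, v) for t, v in obs if not (a <= t <= b)]
        else:
            usable = obs
        grew = False
        m = min_timepoints
        for i in range(len(usable) - m + 1):
            v0, v1 = usable[i][1], usable[i + m - 1][1]
            if v1 >= v0 * (1.0 + min_relative_growth):
                grew = True
                break
        track.status = CLASS_TUBER if grew else CLASS_NONGROWING
        for rec in track.records:
            if rec.object_class == CLASS_CANDIDATE:
                rec.object_class = track.status
    return tracks


_CSV_COLUMNS = [
    "pot_id", "timepoint_days", "label", "volume_mm3", "mean_absorption",
    "cz_mm", "cy_mm", "cx_mm", "a_mm", "b_mm", "c_mm", "aspect_ratio", "class",
]


def records_to_dataframe(records: list[ObjectRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        row = {
            "pot_id": r.pot_id, "timepoint_days": r.timepoint_days, "label": r.label,
            "volume_mm3": r.volume_mm3, "mean_absorption": r.mean_absorption,
            "cz_mm": r.centroid_mm[0], "cy_mm": r.centroid_mm[1], "cx_mm": r.centroid_mm[2],
            "a_mm": r.axis_lengths_mm[0], "b_mm": r.axis_lengths_mm[1], "c_mm": r.axis_lengths_mm[2],
            "aspect_ratio": r.aspect_ratio, "class": r.object_class,
        }
        if r.fresh_weight_g is not None:
            row["fresh_weight_g"] = r.fresh_weight_g
        rows.append(row)
    return pd.DataFrame(rows, columns=_CSV_COLUMNS + (["fresh_weight_g"] if rows and "fresh_weight_g" in rows[0] else []))
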