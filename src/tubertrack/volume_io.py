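"""Reading, writing, and intensity normalization of reconstructed CT volumes.

Supported on-disk dialects:

``mhd``
    MetaImage (``.mhd`` + ``.raw``/``.zraw``), via SimpleITK.
``nrrd``
    NRRD, via SimpleITK.
``tiff_stack``
    A multi-page TIFF (or a directory of per-slice TIFFs) plus a JSON
    sidecar ``<file>.json`` holding the voxel size and metadata.
``raw``
    Flat little-endian float32 voxels plus a JSON sidecar.

All dialects are lossless round-trips for float32 data.  Anisotropic
volumes are rejected: the scanner this pipeline targets reconstructs
isotropic voxels, and every downstream distance/volume computation
assumes a single edge length.

Intensity normalization follows the flat-field idea of referencing each
reconstruction against the unattenuated ("air") signal so the gray-scale
range is comparable across a whole time series.  In the default affine
mode the measured air level is mapped to 0 and the overall gain is
removed by assuming a nominal raw air pedestal (``AIR_RAW_LEVEL``),
which re-expresses volumes on the unit-stable ladder used by all later
thresholds: air = 0, water-like tuber tissue = 1.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .grids import VoxelGrid

log = logging.getLogger(__name__)

__all__ = [
    "AIR_RAW_LEVEL",
    "SeriesManifest",
    "read_volume",
    "write_volume",
    "normalize_intensity",
    "auto_air_region",
    "read_manifest",
    "write_manifest",
]

#: Nominal raw-value pedestal of air regions (reference units).  The phantom
#: scanner model emits ``gain * (AIR_RAW_LEVEL + absorption)``; affine
#: normalization assumes this pedestal to separate gain from offset.
AIR_RAW_LEVEL = 0.2

_ISOTROPY_RTOL = 1e-3


@dataclass
class SeriesManifest:
    """One pot's ordered time series of volume files."""

    pot_id: str
    entries: list[tuple[float, str]]  # (timepoint_days, path)
    condition: str = "control"
    voxel_size_mm: float | None = None

    def __post_init__(self):
        times = [t for t, _ in self.entries]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError(f"timepoints of pot {self.pot_id!r} must be strictly increasing: {times}")

    @property
    def timepoints_days(self) -> list[float]:
        return [t for t, _ in self.entries]


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

_EXT_DIALECT = {
    ".mhd": "mhd",
    ".mha": "mhd",
    ".nrrd": "nrrd",
    ".tif": "tiff_stack",
    ".tiff": "tiff_stack",
    ".raw": "raw",
}


def _infer_dialect(path: Path) -> str:
    if path.is_dir():
        return "tiff_stack"
    try:
        return _EXT_DIALECT[path.suffix.lower()]
    except KeyError:
        raise ValueError(f"cannot infer volume dialect from {path.name!r}") from None


def _sidecar_path(path: Path) -> Path:
    return path.with_name(path.name + ".json")


def _read_sidecar(path: Path) -> dict:
    sc = _sidecar_path(path)
    if not sc.exists():
        raise FileNotFoundError(f"unknown voxel size: sidecar metadata {sc} is missing")
    with open(sc) as fh:
        meta = json.load(fh)
    if "voxel_size_mm" not in meta:
        raise ValueError(f"unknown voxel size: {sc} lacks 'voxel_size_mm'")
    return meta


def _write_sidecar(path: Path, grid: VoxelGrid, extra: dict | None = None) -> None:
    meta = {
        "voxel_size_mm": float(grid.voxel_size_mm),
        "origin_mm": [float(v) for v in grid.origin_mm],
        "normalized": bool(grid.normalized),
        "timepoint_days": float(grid.timepoint_days),
        "pot_id": grid.pot_id,
        "axis_order": "zyx",
    }
    if extra:
        meta.update(extra)
    with open(_sidecar_path(path), "w") as fh:
        json.dump(meta, fh, indent=1)


def _grid_from_meta(data: np.ndarray, meta: dict) -> VoxelGrid:
    return VoxelGrid(
        data=data,
        voxel_size_mm=float(meta["voxel_size_mm"]),
        origin_mm=np.asarray(meta.get("origin_mm", (0.0, 0.0, 0.0)), dtype=float),
        normalized=bool(meta.get("normalized", False)),
        timepoint_days=float(meta.get("timepoint_days", 0.0)),
        pot_id=str(meta.get("pot_id", "")),
    )


def _read_sitk(path: Path) -> VoxelGrid:
    import SimpleITK as sitk

    img = sitk.ReadImage(str(path))
    spacing = np.asarray(img.GetSpacing(), dtype=float)  # (x, y, z)
    if not np.allclose(spacing, spacing[0], rtol=_ISOTROPY_RTOL):
        raise ValueError(f"anisotropic voxels {tuple(spacing)} are not supported (isotropic only)")
    data = sitk.GetArrayFromImage(img)  # (z, y, x)
    origin_xyz = np.asarray(img.GetOrigin(), dtype=float)
    meta = {}
    for key in ("normalized", "timepoint_days", "pot_id"):
        if img.HasMetaDataKey(key):
            meta[key] = img.GetMetaData(key)
    return VoxelGrid(
        data=data,
        voxel_size_mm=float(spacing[0]),
        origin_mm=origin_xyz[::-1],
        normalized=str(meta.get("normalized", "0")) in ("1", "True", "true"),
        timepoint_days=float(meta.get("timepoint_days", 0.0)),
        pot_id=str(meta.get("pot_id", "")),
    )


def _write_sitk(grid: VoxelGrid, path: Path) -> None:
    import SimpleITK as sitk

    img = sitk.GetImageFromArray(np.ascontiguousarray(grid.data))
    img.SetSpacing((grid.voxel_size_mm,) * 3)
    img.SetOrigin(tuple(float(v) for v in grid.origin_mm[::-1]))
    img.SetMetaData("normalized", "1" if grid.normalized else "0")
    img.SetMetaData("timepoint_days", repr(float(grid.timepoint_days)))
    img.SetMetaData("pot_id", grid.pot_id)
    sitk.WriteImage(img, str(path))


def _read_tiff_stack(path: Path) -> VoxelGrid:
    import tifffile

    if path.is_dir():
        slice_files = sorted(p for p in path.iterdir() if p.suffix.lower() in (".tif", ".tiff"))
        if not slice_files:
            raise FileNotFoundError(f"no TIFF slices in {path}")
        slices = [tifffile.imread(p) for p in slice_files]
        shapes = {s.shape for s in slices}
        if len(shapes) > 1:
            bad = next(p.name for p, s in zip(slice_files, slices) if s.shape != slices[0].shape)
            raise ValueError(f"slice extent mismatch in stack {path.name}: offending slice {bad}")
        data = np.stack(slices, axis=0)
        meta = _read_sidecar(path / "stack")
    else:
        with tifffile.TiffFile(path) as tf:
            shapes = [p.shape for p in tf.pages]
            if len(set(shapes)) > 1:
                bad = next(i for i, s in enumerate(shapes) if s != shapes[0])
                raise ValueError(f"slice extent mismatch in {path.name}: offending slice index {bad}")
            data = tf.asarray()
        if data.ndim == 2:
            data = data[None]
        meta = _read_sidecar(path)
    return _grid_from_meta(data, meta)


def _write_tiff_stack(grid: VoxelGrid, path: Path) -> None:
    import tifffile

    tifffile.imwrite(path, np.ascontiguousarray(grid.data))
    _write_sidecar(path, grid)


def _read_raw(path: Path) -> VoxelGrid:
    meta = _read_sidecar(path)
    if "shape" not in meta:
        raise ValueError(f"sidecar for {path.name} lacks 'shape'")
    shape = tuple(int(v) for v in meta["shape"])
    dtype = np.dtype(meta.get("dtype", "<f4"))
    data = np.fromfile(path, dtype=dtype)
    if data.size != int(np.prod(shape)):
        raise ValueError(f"{path.name}: raw payload has {data.size} voxels, sidecar shape {shape} "
                         f"needs {int(np.prod(shape))}")
    return _grid_from_meta(data.reshape(shape), meta)


def _write_raw(grid: VoxelGrid, path: Path) -> None:
    data = np.ascontiguousarray(grid.data, dtype="<f4")
    data.tofile(path)
    _write_sidecar(path, grid, extra={"shape": list(data.shape), "dtype": "<f4"})


def read_volume(path, dialect: str | None = None) -> VoxelGrid:
    """Read a 3D volume; ``dialect`` in {mhd, nrrd, tiff_stack, raw} (inferred if None)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"volume file not found: {path}")
    dialect = dialect or _infer_dialect(path)
    if dialect in ("mhd", "nrrd"):
        return _read_sitk(path)
    if dialect == "tiff_stack":
        return _read_tiff_stack(path)
    if dialect == "raw":
        return _read_raw(path)
    raise ValueError(f"unknown dialect {dialect!r}")


def write_volume(grid: VoxelGrid, path, dialect: str | None = None) -> Path:
    """Write ``grid`` to ``path``; metadata round-trips through :func:`read_volume`."""
    path = Path(path)
    dialect = dialect or _infer_dialect(path)
    if dialect in ("mhd", "nrrd"):
        _write_sitk(grid, path)
    elif dialect == "tiff_stack":
        _write_tiff_stack(grid, path)
    elif dialect == "raw":
        _write_raw(grid, path)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    return path


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

def auto_air_region(grid: VoxelGrid) -> tuple[slice, slice, slice]:
    """Corner octant with the lowest median intensity.

    The pot never occupies all eight corners of the reconstructed box, so
    the darkest corner octant is dominated by unattenuated air.
    """
    nz, ny, nx = grid.shape
    hz, hy, hx = max(nz // 2, 1), max(ny // 2, 1), max(nx // 2, 1)
    best = None
    for sz in (slice(0, hz), slice(nz - hz, nz)):
        for sy in (slice(0, hy), slice(ny - hy, ny)):
            for sx in (slice(0, hx), slice(nx - hx, nx)):
                med = float(np.median(grid.data[sz, sy, sx]))
                if best is None or med < best[0]:
                    best = (med, (sz, sy, sx))
    return best[1]


def _auto_air_mean(grid: VoxelGrid) -> float:
    """Robust air level from the darkest corner octant.

    The octant still contains part of the pot, so the plain octant mean
    is biased; instead the air sample is the voxels within a MAD-based
    window around the octant median (soil and pot material sit far above
    it), and the air level is their mean.
    """
    region = grid.data[auto_air_region(grid)]
    med = float(np.median(region))
    mad_sd = 1.4826 * float(np.median(np.abs(region - med)))
    if mad_sd == 0.0:
        return med
    sample = region[np.abs(region - med) <= 4.0 * mad_sd]
    return float(sample.mean())


def normalize_intensity(
    grid: VoxelGrid,
    air_region="auto",
    air_target: float = 0.0,
    mode: str = "affine",
    air_level: float = AIR_RAW_LEVEL,
    zero_tol: float = 1e-9,
) -> VoxelGrid:
    """Rescale intensities so the mean of the air region equals ``air_target``.

    Parameters
    ----------
    air_region
        ``"auto"`` (darkest corner octant) or a box of voxel index ranges
        ``((z0, z1), (y0, y1), (x0, x1))``.
    air_target
        Desired mean intensity of the air region after normalization.
    mode
        ``"affine"`` (default): scale by ``air_level / air_mean`` (removing
        the scan gain under the nominal-pedestal assumption) then shift the
        air level to ``air_target``.
        ``"multiplicative"``: pure scaling ``data * air_target / air_mean``
        (requires a nonzero ``air_target``).
    air_level
        Assumed raw air pedestal in reference units (affine mode only).
    """
    if not np.isfinite(air_target):
        raise ValueError("air_target must be finite")
    if air_region == "auto":
        air_mean = _auto_air_mean(grid)
    else:
        region = tuple(slice(int(a), int(b)) for a, b in air_region)
        air = grid.data[region]
        if air.size == 0:
            raise ValueError("air region is empty")
        air_mean = float(air.mean())

    scale_ref = air_target if mode == "multiplicative" else air_level
    if abs(air_mean - air_target) <= zero_tol + 1e-3 * abs(scale_ref):
        # already normalized: second application is a no-op (idempotence)
        return grid.with_data(grid.data.copy(), normalized=True)

    if abs(air_mean) <= zero_tol:
        raise ValueError("cannot normalize against zero baseline (air mean ~ 0)")

    if mode == "multiplicative":
        if abs(air_target) <= zero_tol:
            raise ValueError("multiplicative normalization needs a nonzero air_target")
        scale = air_target / air_mean
        out = grid.data * scale
        log.info("normalize_intensity pot=%s t=%.3g: multiplicative scale=%.6g (air mean %.6g -> %.6g)",
                 grid.pot_id, grid.timepoint_days, scale, air_mean, air_target)
    elif mode == "affine":
        scale = air_level / air_mean
        out = grid.data * scale - air_level + air_target
        log.info("normalize_intensity pot=%s t=%.3g: affine scale=%.6g offset=%.6g (air mean %.6g -> %.6g)",
                 grid.pot_id, grid.timepoint_days, scale, air_target - air_level, air_mean, air_target)
    else:
        raise ValueError(f"unknown normalization mode {mode!r}")
    return grid.with_data(out.astype(grid.data.dtype, copy=False), normalized=True)


# ---------------------------------------------------------------------------
# manifests
# ---------------------------------------------------------------------------

def read_manifest(path) -> list[SeriesManifest]:
    """Read a series manifest CSV (pot_id, timepoint_days, path, condition)."""
    df = pd.read_csv(path)
    required = {"pot_id", "timepoint_days", "path"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"manifest {path} missing columns {sorted(missing)}")
    if "condition" not in df.columns:
        df["condition"] = "control"
    manifests = []
    for pot_id, sub in df.groupby("pot_id", sort=True):
        sub = sub.sort_values("timepoint_days")
        conditions = sub["condition"].unique()
        if len(conditions) > 1:
            raise ValueError(f"pot {pot_id!r} has conflicting conditions {list(conditions)}")
        voxel = None
        if "voxel_size_mm" in sub.columns:
            vox = sub["voxel_size_mm"].unique()
            if len(vox) > 1:
                raise ValueError(f"pot {pot_id!r} mixes voxel sizes {list(vox)}")
            voxel = float(vox[0])
        manifests.append(SeriesManifest(
            pot_id=str(pot_id),
            entries=[(float(t), str(p)) for t, p in zip(sub["timepoint_days"], sub["path"])],
            condition=str(conditions[0]),
            voxel_size_mm=voxel,
        ))
    return manifests


def write_manifest(manifests: list[SeriesManifest], path) -> Path:
    rows = []
    for m in manifests:
        for t, p in m.entries:
            row = {"pot_id": m.pot_id, "timepoint_days": t, "path": p, "condition": m.condition}
            if m.voxel_size_mm is not None:
                row["voxel_size_mm"] = m.voxel_size_mm
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)
    return Path(path)
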