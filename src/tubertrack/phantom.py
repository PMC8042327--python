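"""Synthetic 4D pot phantoms with ground truth.

The generator stands in for the CT scanner: it renders, per timepoint, a
reconstructed-absorption volume of a soil-filled pot containing growing
tubers plus the confounders the segmentation stage must survive —
granular (spatially inhomogeneous) soil, tangentially attached stolons,
dense homogeneous stones, the pot wall, air background, a slow
moisture-driven drift of the soil level, and per-scan source-gain
variation plus voxel noise.

Scene properties mirror the measurement physics the pipeline exploits:

* soil is a correlated random field (Gaussian-smoothed white noise with
  a stated correlation length), so its local variance is high;
* tubers are analytic near-ellipsoids of uniform absorption ~ 1.0
  (water/starch-like), so their local variance is low;
* stones sit at absorption ~ 1.8 (denser mineral), stolons share tuber
  absorption but are elongated tubes;
* object boundaries are anti-aliased with the partial-volume fraction of
  each voxel, since millimeter-scale detectability is only meaningful
  with realistic soft edges.

Absorption ladder (normalized units): air 0.0, soil mean 0.6 with
heterogeneity, tuber/stolon 1.0, stone 1.8.  Raw (un-normalized) scanner
output is ``gain * (AIR_RAW_LEVEL + absorption + noise)``.

Ground truth comes from the analytic shapes, never from the noisy
voxels: true volumes follow the growth model, true mass is a constant
tissue density times true volume.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .grids import LabelGrid, VoxelGrid
from .volume_io import AIR_RAW_LEVEL, SeriesManifest

__all__ = [
    "DENSITY_G_PER_MM3",
    "LABEL_SOIL", "LABEL_POT", "STOLON_LABEL_BASE", "STONE_LABEL_BASE",
    "GrowthModel", "TuberSpec", "StolonSpec", "StoneSpec", "SoilSpec", "PotSpec",
    "SceneSpec", "GroundTruthFrame", "GroundTruth",
    "render_scene", "render_series", "scene_to_dict", "scene_from_dict",
    "default_scene", "default_experiment", "single_sphere_scene",
]

#: Fresh tissue density of potato tubers (1.09 g/cm^3), used for true mass.
DENSITY_G_PER_MM3 = 1.09e-3

# class-coded ground-truth labels; tuber ids occupy 1..N
LABEL_SOIL = 1000
LABEL_POT = 1001
STOLON_LABEL_BASE = 2000
STONE_LABEL_BASE = 3000


# ---------------------------------------------------------------------------
# scene specification
# ---------------------------------------------------------------------------

@dataclass
class GrowthModel:
    """Logistic tuber volume growth, optionally with a stress-arrest window.

    ``dV/dt = rate * V * (1 - V/capacity) * m(t)`` where ``m(t)`` equals
    ``arrest_factor`` inside ``arrest_window`` and 1 elsewhere.  Solved
    exactly through the effective time ``tau(t) = integral of m``, so the
    volume curve is continuous and, for ``arrest_factor >= 0``,
    non-decreasing.
    """

    kind: str = "logistic"  # "logistic" | "logistic_with_arrest"
    initial_volume_mm3: float = 150.0
    rate_per_day: float = 0.15
    capacity_mm3: float = 2000.0
    arrest_window: tuple[float, float] | None = None
    arrest_factor: float = 0.0

    def __post_init__(self):
        if self.kind not in ("logistic", "logistic_with_arrest"):
            raise ValueError(f"unknown growth model kind {self.kind!r}")
        if self.kind == "logistic_with_arrest" and self.arrest_window is None:
            raise ValueError("logistic_with_arrest needs an arrest_window")
        if not 0.0 <= self.arrest_factor <= 1.0:
            raise ValueError("arrest_factor must lie in [0, 1]")
        if self.initial_volume_mm3 <= 0 or self.capacity_mm3 <= self.initial_volume_mm3:
            raise ValueError("need 0 < initial_volume_mm3 < capacity_mm3")

    def _effective_time(self, t: float) -> float:
        if self.kind == "logistic" or self.arrest_window is None:
            return t
        a, b = self.arrest_window
        inside = max(0.0, min(t, b) - a)
        return t - inside * (1.0 - self.arrest_factor)

    def volume_mm3(self, t_days: float) -> float:
        tau = self._effective_time(float(t_days))
        v0, k, r = self.initial_volume_mm3, self.capacity_mm3, self.rate_per_day
        return k * v0 / (v0 + (k - v0) * np.exp(-r * tau))


@dataclass
class TuberSpec:
    center_mm: tuple[float, float, float]  # (z, y, x)
    semi_axes_mm: tuple[float, float, float]  # principal semi-axes at t=0
    absorption: float = 1.0
    growth: GrowthModel = field(default_factory=GrowthModel)

    def semi_axes_at(self, t_days: float) -> np.ndarray:
        """Semi-axes scaled isotropically so the ellipsoid volume tracks the growth model."""
        axes0 = np.asarray(self.semi_axes_mm, dtype=float)
        v0 = 4.0 / 3.0 * np.pi * np.prod(axes0)
        scale = (self.growth.volume_mm3(t_days) / self.growth.volume_mm3(0.0)) ** (1.0 / 3.0)
        # anchor t=0 axes to the growth model's initial volume
        base = (self.growth.initial_volume_mm3 / v0) ** (1.0 / 3.0)
        return axes0 * base * scale

    def volume_mm3(self, t_days: float) -> float:
        return self.growth.volume_mm3(t_days)


@dataclass
class StolonSpec:
    polyline_mm: list[tuple[float, float, float]]  # (z, y, x) vertices
    radius_mm: float = 1.2
    absorption: float = 1.0


@dataclass
class StoneSpec:
    center_mm: tuple[float, float, float]
    semi_axes_mm: tuple[float, float, float]
    absorption: float = 1.8


@dataclass
class SoilSpec:
    mean_absorption: float = 0.6
    heterogeneity_sd: float = 0.15
    correlation_length_mm: float = 1.0
    moisture_drift_per_day: float = 0.0  # additive change of the soil mean per day


@dataclass
class PotSpec:
    """Cylindrical pot, axis along z."""

    center_yx_mm: tuple[float, float]
    inner_radius_mm: float
    wall_thickness_mm: float = 1.2
    bottom_mm: float = 2.0       # z of the inner pot floor
    soil_top_mm: float = 40.0    # z of the soil surface
    wall_top_mm: float = 44.0    # z of the pot rim
    wall_absorption: float = 1.6


@dataclass
class SceneSpec:
    """Full description of one simulated pot; with a seed it renders bitwise-reproducibly."""

    shape_vox: tuple[int, int, int]
    voxel_size_mm: float
    soil: SoilSpec = field(default_factory=SoilSpec)
    tubers: list[TuberSpec] = field(default_factory=list)
    stolons: list[StolonSpec] = field(default_factory=list)
    stones: list[StoneSpec] = field(default_factory=list)
    pot: PotSpec | None = None   # None: soil fills the whole box (cropped sub-volume)
    timepoints_days: list[float] = field(default_factory=lambda: [0.0])
    noise_sigma: float = 0.02          # additive voxel noise, absorption units
    mult_noise_sd: float = 0.0         # multiplicative intensity noise (fractional sd)
    gain_jitter_sd: float = 0.05       # per-scan source-gain variation (fractional sd)
    pot_id: str = "pot"
    condition: str = "control"
    seed: int = 0

    def __post_init__(self):
        if len(self.timepoints_days) >= 1:
            t = list(self.timepoints_days)
            if any(b <= a for a, b in zip(t, t[1:])):
                raise ValueError("timepoints_days must be strictly increasing")
        if self.voxel_size_mm <= 0:
            raise ValueError("voxel_size_mm must be positive")


@dataclass
class GroundTruthFrame:
    """Analytic truth for one timepoint."""

    labels: LabelGrid
    tubers: pd.DataFrame  # tuber_id, true_volume_mm3, true_mass_g, cz/cy/cx_mm, a/b/c_mm


@dataclass
class GroundTruth:
    frames: list[GroundTruthFrame]

    @property
    def tubers(self) -> pd.DataFrame:
        return pd.concat([f.tubers for f in self.frames], ignore_index=True)


# ---------------------------------------------------------------------------
# rasterization helpers
# ---------------------------------------------------------------------------

def _axis_coords(n: int, voxel: float) -> np.ndarray:
    return (np.arange(n) + 0.5) * voxel


def _ellipsoid_fraction(spec: SceneSpec, center, semi_axes):
    """Partial-volume fraction of an analytic ellipsoid on the voxel lattice.

    Returns (bounding slices, fraction array).  The fraction is a linear
    ramp over one voxel width around the surface, using the first-order
    signed distance ``(1 - rho) / |grad rho|`` of the normalized radius.
    """
    vox = spec.voxel_size_mm
    center = np.asarray(center, dtype=float)
    axes = np.asarray(semi_axes, dtype=float)
    lo = np.maximum(np.floor((center - axes) / vox - 2).astype(int), 0)
    hi = np.minimum(np.ceil((center + axes) / vox + 2).astype(int), np.asarray(spec.shape_vox))
    if np.any(hi <= lo):
        return tuple(slice(a, b) for a, b in zip(lo, hi)), np.zeros(np.maximum(hi - lo, 0), dtype=np.float32)
    sl = tuple(slice(a, b) for a, b in zip(lo, hi))
    zz = _axis_coords(spec.shape_vox[0], vox)[sl[0]][:, None, None] - center[0]
    yy = _axis_coords(spec.shape_vox[1], vox)[sl[1]][None, :, None] - center[1]
    xx = _axis_coords(spec.shape_vox[2], vox)[sl[2]][None, None, :] - center[2]
    u, v, w = zz / axes[0], yy / axes[1], xx / axes[2]
    rho = np.sqrt(u * u + v * v + w * w)
    # |grad rho| in mm^-1; guard the center where rho -> 0
    grad = np.sqrt((u / axes[0]) ** 2 + (v / axes[1]) ** 2 + (w / axes[2]) ** 2) / np.maximum(rho, 1e-9)
    dist_mm = (1.0 - rho) / np.maximum(grad, 1e-9)
    frac = np.clip(0.5 + dist_mm / vox, 0.0, 1.0).astype(np.float32)
    return sl, frac


def _capsule_fraction(spec: SceneSpec, polyline, radius_mm):
    """Partial-volume fraction of a tube (capsule chain) around a polyline."""
    vox = spec.voxel_size_mm
    pts = np.asarray(polyline, dtype=float)
    lo = np.maximum(np.floor((pts.min(axis=0) - radius_mm) / vox - 2).astype(int), 0)
    hi = np.minimum(np.ceil((pts.max(axis=0) + radius_mm) / vox + 2).astype(int), np.asarray(spec.shape_vox))
    sl = tuple(slice(a, b) for a, b in zip(lo, hi))
    zz = _axis_coords(spec.shape_vox[0], vox)[sl[0]][:, None, None]
    yy = _axis_coords(spec.shape_vox[1], vox)[sl[1]][None, :, None]
    xx = _axis_coords(spec.shape_vox[2], vox)[sl[2]][None, None, :]
    shape = np.broadcast_shapes(zz.shape, yy.shape, xx.shape)
    dmin = np.full(shape, np.inf, dtype=np.float64)
    p = np.stack(np.broadcast_arrays(zz, yy, xx), axis=-1)
    for a, b in zip(pts[:-1], pts[1:]):
        ab = b - a
        denom = float(ab @ ab)
        if denom == 0.0:
            proj = np.zeros(shape)
        else:
            proj = np.clip(((p - a) @ ab) / denom, 0.0, 1.0)
        closest = a + proj[..., None] * ab
        d = np.linalg.norm(p - closest, axis=-1)
        np.minimum(dmin, d, out=dmin)
    frac = np.clip(0.5 + (radius_mm - dmin) / vox, 0.0, 1.0).astype(np.float32)
    return sl, frac


def _paint(absorption, labels, sl, frac, value, label):
    """Blend an object into the absorption field and stamp its truth label."""
    region = absorption[sl]
    absorption[sl] = frac * value + (1.0 - frac) * region
    labels[sl][frac >= 0.5] = label


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def _soil_field(spec: SceneSpec) -> np.ndarray:
    """Static correlated heterogeneity field (zero mean, target sd)."""
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 101]))
    white = rng.standard_normal(spec.shape_vox).astype(np.float32)
    sigma_vox = spec.soil.correlation_length_mm / spec.voxel_size_mm
    smooth = ndi.gaussian_filter(white, sigma_vox, mode="reflect")
    sd = float(smooth.std())
    if sd > 0:
        smooth *= spec.soil.heterogeneity_sd / sd
    return smooth


def _scene_masks(spec: SceneSpec):
    """(soil mask, pot-wall mask) for the scene geometry."""
    nz, ny, nx = spec.shape_vox
    vox = spec.voxel_size_mm
    if spec.pot is None:
        return np.ones(spec.shape_vox, dtype=bool), np.zeros(spec.shape_vox, dtype=bool)
    pot = spec.pot
    zz = _axis_coords(nz, vox)[:, None, None]
    yy = _axis_coords(ny, vox)[None, :, None] - pot.center_yx_mm[0]
    xx = _axis_coords(nx, vox)[None, None, :] - pot.center_yx_mm[1]
    r = np.sqrt(yy * yy + xx * xx)
    inner = r <= pot.inner_radius_mm
    outer = r <= pot.inner_radius_mm + pot.wall_thickness_mm
    soil = inner & (zz >= pot.bottom_mm) & (zz <= pot.soil_top_mm)
    wall_side = outer & ~inner & (zz >= pot.bottom_mm - pot.wall_thickness_mm) & (zz <= pot.wall_top_mm)
    wall_bottom = outer & (zz >= pot.bottom_mm - pot.wall_thickness_mm) & (zz < pot.bottom_mm)
    return soil, (wall_side | wall_bottom)


def _check_objects_inside(spec: SceneSpec) -> None:
    if spec.pot is None:
        return
    pot = spec.pot
    t_end = spec.timepoints_days[-1]
    for i, tb in enumerate(spec.tubers):
        axes = tb.semi_axes_at(t_end)
        cz, cy, cx = tb.center_mm
        r = np.hypot(cy - pot.center_yx_mm[0], cx - pot.center_yx_mm[1])
        if (r + max(axes[1], axes[2]) > pot.inner_radius_mm
                or cz - axes[0] < pot.bottom_mm or cz + axes[0] > pot.soil_top_mm):
            raise ValueError(f"tuber {i} leaves the pot at its final size")
    for i, st in enumerate(spec.stones):
        cz, cy, cx = st.center_mm
        r = np.hypot(cy - pot.center_yx_mm[0], cx - pot.center_yx_mm[1])
        if r + max(st.semi_axes_mm) > pot.inner_radius_mm:
            raise ValueError(f"stone {i} leaves the pot")


def _truth_row(spec: SceneSpec, tuber_id: int, tb: TuberSpec, t: float) -> dict:
    axes = tb.semi_axes_at(t)
    vol = 4.0 / 3.0 * np.pi * float(np.prod(axes))
    cz, cy, cx = tb.center_mm
    return {
        "pot_id": spec.pot_id, "condition": spec.condition, "timepoint_days": t,
        "tuber_id": tuber_id, "true_volume_mm3": vol, "true_mass_g": DENSITY_G_PER_MM3 * vol,
        "cz_mm": cz, "cy_mm": cy, "cx_mm": cx,
        "a_mm": float(axes.max()), "b_mm": float(np.median(axes)), "c_mm": float(axes.min()),
    }


def render_scene(
    spec: SceneSpec,
    timepoint_days: float,
    normalized: bool = False,
    _soil: np.ndarray | None = None,
) -> tuple[VoxelGrid, GroundTruthFrame]:
    """Render one timepoint of the scene.

    With ``normalized=False`` (default) the volume carries the raw scanner
    model ``gain * (AIR_RAW_LEVEL + absorption + noise)``; with
    ``normalized=True`` it is already on the air=0 ladder (as a cropped,
    flat-field-corrected sub-volume would be).
    """
    t0, t1 = spec.timepoints_days[0], spec.timepoints_days[-1]
    if not (t0 <= timepoint_days <= t1):
        raise ValueError(f"timepoint {timepoint_days} outside simulated range [{t0}, {t1}]")
    _check_objects_inside(spec)
    t = float(timepoint_days)
    try:
        t_index = spec.timepoints_days.index(timepoint_days)
    except ValueError:
        t_index = int(round(timepoint_days * 1000))

    absorption = np.zeros(spec.shape_vox, dtype=np.float32)
    labels = np.zeros(spec.shape_vox, dtype=np.int32)

    soil_mask, wall_mask = _scene_masks(spec)
    soil_field = _soil if _soil is not None else _soil_field(spec)
    soil_mean_t = spec.soil.mean_absorption + spec.soil.moisture_drift_per_day * t
    absorption[soil_mask] = soil_mean_t + soil_field[soil_mask]
    labels[soil_mask] = LABEL_SOIL
    if spec.pot is not None:
        absorption[wall_mask] = spec.pot.wall_absorption
        labels[wall_mask] = LABEL_POT

    for k, stone in enumerate(spec.stones):
        sl, frac = _ellipsoid_fraction(spec, stone.center_mm, stone.semi_axes_mm)
        _paint(absorption, labels, sl, frac, stone.absorption, STONE_LABEL_BASE + k)
    for k, stolon in enumerate(spec.stolons):
        sl, frac = _capsule_fraction(spec, stolon.polyline_mm, stolon.radius_mm)
        _paint(absorption, labels, sl, frac, stolon.absorption, STOLON_LABEL_BASE + k)
    rows = []
    for i, tb in enumerate(spec.tubers, start=1):
        sl, frac = _ellipsoid_fraction(spec, tb.center_mm, tb.semi_axes_at(t))
        core = frac >= 0.5
        clash = labels[sl][core]
        if np.any((clash >= 1) & (clash < STOLON_LABEL_BASE) & (clash != LABEL_SOIL) & (clash != LABEL_POT)):
            raise ValueError(f"tuber {i} overlaps another tuber at t={t}")
        _paint(absorption, labels, sl, frac, tb.absorption, i)
        rows.append(_truth_row(spec, i, tb, t))

    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 7, t_index]))
    data = absorption
    if spec.mult_noise_sd > 0:
        data = data * (1.0 + spec.mult_noise_sd * rng.standard_normal(spec.shape_vox).astype(np.float32))
    if spec.noise_sigma > 0:
        data = data + spec.noise_sigma * rng.standard_normal(spec.shape_vox).astype(np.float32)
    if normalized:
        out = data
    else:
        gain = 1.0 + spec.gain_jitter_sd * float(rng.standard_normal())
        out = gain * (AIR_RAW_LEVEL + data)

    grid = VoxelGrid(out.astype(np.float32), spec.voxel_size_mm, normalized=normalized,
                     timepoint_days=t, pot_id=spec.pot_id)
    truth = GroundTruthFrame(
        labels=LabelGrid(labels, spec.voxel_size_mm, timepoint_days=t, pot_id=spec.pot_id),
        tubers=pd.DataFrame(rows, columns=[
            "pot_id", "condition", "timepoint_days", "tuber_id", "true_volume_mm3",
            "true_mass_g", "cz_mm", "cy_mm", "cx_mm", "a_mm", "b_mm", "c_mm"]),
    )
    return grid, truth


def render_series(
    spec: SceneSpec, normalized: bool = False
) -> tuple[SeriesManifest, list[VoxelGrid], GroundTruth]:
    """Render all timepoints of the scene; the soil texture is static, noise and gain per scan."""
    if len(spec.timepoints_days) < 2:
        raise ValueError("a series needs at least 2 timepoints")
    soil = _soil_field(spec)
    grids, frames = [], []
    for t in spec.timepoints_days:
        g, f = render_scene(spec, t, normalized=normalized, _soil=soil)
        grids.append(g)
        frames.append(f)
    manifest = SeriesManifest(
        pot_id=spec.pot_id,
        entries=[(float(t), "") for t in spec.timepoints_days],
        condition=spec.condition,
        voxel_size_mm=spec.voxel_size_mm,
    )
    return manifest, grids, GroundTruth(frames)


# ---------------------------------------------------------------------------
# (de)serialization of scene specs
# ---------------------------------------------------------------------------

def scene_to_dict(spec: SceneSpec) -> dict:
    """Plain-data form of a scene spec, suitable for YAML/TOML configs."""
    import dataclasses

    d = dataclasses.asdict(spec)
    for tb, src in zip(d["tubers"], spec.tubers):
        tb["growth"] = dataclasses.asdict(src.growth)
    return d


def scene_from_dict(d: dict) -> SceneSpec:
    d = dict(d)
    d["shape_vox"] = tuple(int(v) for v in d["shape_vox"])
    if d.get("soil") is not None:
        d["soil"] = SoilSpec(**d["soil"])
    if d.get("pot") is not None:
        pot = dict(d["pot"])
        pot["center_yx_mm"] = tuple(pot["center_yx_mm"])
        d["pot"] = PotSpec(**pot)
    tubers = []
    for tb in d.get("tubers", []):
        tb = dict(tb)
        growth = dict(tb.pop("growth", {}))
        if growth.get("arrest_window") is not None:
            growth["arrest_window"] = tuple(growth["arrest_window"])
        tb["center_mm"] = tuple(tb["center_mm"])
        tb["semi_axes_mm"] = tuple(tb["semi_axes_mm"])
        tubers.append(TuberSpec(growth=GrowthModel(**growth), **tb))
    d["tubers"] = tubers
    d["stolons"] = [StolonSpec(polyline_mm=[tuple(p) for p in s["polyline_mm"]],
                               radius_mm=s.get("radius_mm", 1.2),
                               absorption=s.get("absorption", 1.0))
                    for s in d.get("stolons", [])]
    d["stones"] = [StoneSpec(center_mm=tuple(s["center_mm"]),
                             semi_axes_mm=tuple(s["semi_axes_mm"]),
                             absorption=s.get("absorption", 1.8))
                   for s in d.get("stones", [])]
    return SceneSpec(**d)


# ---------------------------------------------------------------------------
# stock scenes
# ---------------------------------------------------------------------------

def default_scene(
    condition: str = "control",
    pot_id: str | None = None,
    seed: int = 0,
    timepoints_days: list[float] | None = None,
    voxel_size_mm: float = 0.4,
) -> SceneSpec:
    """The standard desk-scale pot: 3 growing tubers, 1 stone, 1 tangent stolon.

    The stress condition arrests tuber growth between days 15 and 29 and
    adds a slow drying drift to the soil mean; control pots grow
    uninterrupted with stable moisture.
    """
    if timepoints_days is None:
        timepoints_days = [1, 5, 8, 12, 15, 19, 22, 26, 29, 33, 36, 40]
    timepoints_days = [float(t) for t in timepoints_days]
    stress = condition == "stress"
    arrest = dict(kind="logistic_with_arrest", arrest_window=(15.0, 29.0), arrest_factor=0.0) if stress else {}
    pot = PotSpec(center_yx_mm=(24.0, 24.0), inner_radius_mm=20.0, wall_thickness_mm=1.2,
                  bottom_mm=3.0, soil_top_mm=40.0, wall_top_mm=44.0)
    tubers = [
        TuberSpec(center_mm=(14.0, 15.0, 16.0), semi_axes_mm=(4.0, 3.4, 3.2),
                  growth=GrowthModel(initial_volume_mm3=170.0, rate_per_day=0.16,
                                     capacity_mm3=2300.0, **arrest)),
        TuberSpec(center_mm=(25.0, 31.0, 20.0), semi_axes_mm=(3.3, 3.3, 3.8),
                  growth=GrowthModel(initial_volume_mm3=150.0, rate_per_day=0.13,
                                     capacity_mm3=1700.0, **arrest)),
        TuberSpec(center_mm=(31.0, 17.0, 30.0), semi_axes_mm=(3.6, 3.2, 3.6),
                  growth=GrowthModel(initial_volume_mm3=190.0, rate_per_day=0.18,
                                     capacity_mm3=2000.0, **arrest)),
    ]
    # stolon attached tangentially to tuber 1; it stays still while the tuber grows
    stolons = [StolonSpec(polyline_mm=[(14.0, 15.0, 21.0), (17.0, 18.0, 28.0), (22.0, 21.0, 34.0)],
                          radius_mm=1.2)]
    stones = [StoneSpec(center_mm=(12.0, 32.0, 33.0), semi_axes_mm=(4.0, 3.5, 3.0))]
    soil = SoilSpec(mean_absorption=0.62, heterogeneity_sd=0.15, correlation_length_mm=1.0,
                    moisture_drift_per_day=-0.003 if stress else 0.0)
    return SceneSpec(
        shape_vox=(120, 120, 120), voxel_size_mm=voxel_size_mm, soil=soil,
        tubers=tubers, stolons=stolons, stones=stones, pot=pot,
        timepoints_days=timepoints_days, noise_sigma=0.02,
        pot_id=pot_id or f"{condition}-{seed}", condition=condition, seed=seed,
    )


def default_experiment(seed: int = 0, pots_per_condition: int = 1) -> list[SceneSpec]:
    """Paired control/stress pots sharing one acquisition protocol."""
    specs = []
    for c, condition in enumerate(("control", "stress")):
        for p in range(pots_per_condition):
            specs.append(default_scene(condition=condition, seed=seed + 31 * c + 7 * p + 1,
                                       pot_id=f"{condition}-{p}"))
    return specs


def single_sphere_scene(
    diameter_mm: float,
    voxel_size_mm: float = 0.0889,
    shape_vox: tuple[int, int, int] = (160, 160, 160),
    seed: int = 0,
    noise_sigma: float = 0.02,
    mult_noise_sd: float = 0.0,
    margin_mm: float | None = None,
) -> SceneSpec:
    """A cropped all-soil sub-volume with one spherical tuber at its center.

    Emulates a sub-volume cut from inside the pot (no air, no wall), the
    geometry used for small-object detectability and calibration studies.
    """
    shape = np.asarray(shape_vox)
    extent = shape * voxel_size_mm
    if np.any(diameter_mm >= extent - 2 * voxel_size_mm):
        raise ValueError(f"sphere of {diameter_mm} mm does not fit the {tuple(extent)} mm box")
    r = diameter_mm / 2.0
    center = tuple(extent / 2.0)
    vol = 4.0 / 3.0 * np.pi * r ** 3
    tuber = TuberSpec(center_mm=center, semi_axes_mm=(r, r, r),
                      growth=GrowthModel(initial_volume_mm3=vol, capacity_mm3=vol * 10.0))
    return SceneSpec(
        shape_vox=tuple(int(n) for n in shape_vox), voxel_size_mm=voxel_size_mm,
        soil=SoilSpec(), tubers=[tuber], pot=None,
        timepoints_days=[0.0, 1.0], noise_sigma=noise_sigma, mult_noise_sd=mult_noise_sd,
        pot_id=f"sphere-{diameter_mm:g}mm-{seed}", seed=seed,
    )
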