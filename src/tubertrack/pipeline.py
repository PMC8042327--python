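"""End-to-end orchestration: normalize -> segment -> features -> filters ->
track -> growth-filter -> calibrate -> growth analytics.

One :class:`RunConfig` governs an entire experiment; it is serialized
verbatim into every output directory for provenance, and the frozen
segmentation parameter set (variance threshold calibrated once on the
first volume) is shared by every pot, timepoint, and condition.
The analysis path is deterministic and seed-free; randomness exists only
in the phantom generator.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import volume_io
from .features import (CLASS_CANDIDATE, CLASS_TUBER, classify_absorption, classify_aspect,
                       classify_growth, extract_features, records_to_dataframe)
from .grids import LabelGrid, VoxelGrid
from .growth import (CalibrationModel, GrowthCurve, apply_calibration, fit_calibration,
                     group_summary, plant_totals_and_velocity, virtual_fresh_weight)
from .segmentation import SegmentationParams, resolve_params, segment_volume
from .tracking import TuberTrack, build_tracks, tracks_to_dataframe
from .volume_io import SeriesManifest, normalize_intensity, read_volume, write_volume

log = logging.getLogger(__name__)

__all__ = ["RunConfig", "PotResult", "RunResult", "analyze_pot", "run_pipeline",
           "load_config", "save_config"]


@dataclass
class RunConfig:
    """One experiment-wide configuration."""

    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    absorption_band: tuple[float, float] = (0.8, 1.3)
    max_aspect: float = 3.0
    growth_min_timepoints: int = 3
    growth_min_relative: float = 0.05
    stress_window: tuple[float, float] | None = None
    tracking_max_gap: int = 1
    normalization_mode: str = "affine"
    air_target: float = 0.0
    calibration_slope: float | None = None
    calibration_intercept: float = 0.0
    calibration_csv: str | None = None
    calibration_through_origin: bool = False
    seed: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["segmentation"] = dataclasses.asdict(self.segmentation)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        seg = d.pop("segmentation", {})
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(segmentation=SegmentationParams(**seg), **d)
        if cfg.stress_window is not None:
            cfg.stress_window = tuple(float(v) for v in cfg.stress_window)
        cfg.absorption_band = tuple(float(v) for v in cfg.absorption_band)
        return cfg


def load_config(path) -> RunConfig:
    with open(path) as fh:
        return RunConfig.from_dict(yaml.safe_load(fh) or {})


def save_config(config: RunConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)


@dataclass
class PotResult:
    pot_id: str
    condition: str
    labels_by_timepoint: list[LabelGrid]
    records_by_timepoint: list[list]
    tracks: list[TuberTrack]
    curves: GrowthCurve


@dataclass
class RunResult:
    pots: list[PotResult]
    params: SegmentationParams
    calibration: CalibrationModel | None
    group: pd.DataFrame


def _resolve_calibration(config: RunConfig) -> CalibrationModel | None:
    if config.calibration_csv:
        df = pd.read_csv(config.calibration_csv)
        if "vfw" in df.columns:
            vfw = df["vfw"].to_numpy(float)
        elif {"volume_mm3", "mean_absorption"} <= set(df.columns):
            vfw = (df["volume_mm3"] * df["mean_absorption"]).to_numpy(float)
        else:
            raise ValueError("calibration CSV needs a 'vfw' column or volume_mm3 + mean_absorption")
        model = fit_calibration(vfw, df["measured_mass_g"].to_numpy(float),
                                through_origin=config.calibration_through_origin)
        log.info("calibration fitted: slope=%.4g intercept=%.4g R2=%.4f (n=%d)",
                 model.slope, model.intercept, model.r_squared, model.n_points)
        return model
    if config.calibration_slope is not None:
        return CalibrationModel(slope=config.calibration_slope,
                                intercept=config.calibration_intercept,
                                r_squared=float("nan"), n_points=0, residual_sd=float("nan"))
    return None


def analyze_pot(
    grids: list[VoxelGrid],
    config: RunConfig,
    params: SegmentationParams,
    calibration: CalibrationModel | None,
    condition: str = "control",
) -> PotResult:
    """Segment, filter, track, and analyze one pot's normalized time series."""
    labels_by_t, records_by_t = [], []
    for grid in grids:
        labels = segment_volume(grid, params)
        records = extract_features(grid, labels)
        classify_absorption(records, config.absorption_band)
        classify_aspect(records, config.max_aspect)
        n_cand = sum(r.object_class == CLASS_CANDIDATE for r in records)
        log.info("pot=%s t=%.3g: %d objects, %d candidates after absorption/aspect",
                 grid.pot_id, grid.timepoint_days, len(records), n_cand)
        labels_by_t.append(labels)
        records_by_t.append(records)
    tracks = build_tracks(records_by_t, max_gap=config.tracking_max_gap)
    classify_growth(tracks, config.growth_min_timepoints, config.growth_min_relative,
                    config.stress_window)
    n_tubers = sum(t.status == CLASS_TUBER for t in tracks)
    log.info("pot=%s: %d tracks, %d accepted as tubers", grids[0].pot_id, len(tracks), n_tubers)
    if calibration is not None:
        for recs in records_by_t:
            apply_calibration(calibration, recs)
    weight_field = "fresh_weight_g" if calibration is not None else "vfw"
    curves = plant_totals_and_velocity(tracks, weight_field=weight_field)
    return PotResult(pot_id=grids[0].pot_id, condition=condition,
                     labels_by_timepoint=labels_by_t, records_by_timepoint=records_by_t,
                     tracks=tracks, curves=curves)


def run_pipeline(
    config: RunConfig,
    manifests: list[SeriesManifest] | str | Path,
    out_dir: str | Path | None = None,
    volumes: dict[str, list[VoxelGrid]] | None = None,
    write_labels: bool = True,
) -> RunResult:
    """Run the whole experiment over one or more pots.

    ``manifests`` may be a manifest CSV path or in-memory manifests; with
    ``volumes`` given (pot_id -> grids) the file paths are ignored, which
    is how phantom series are analyzed without touching disk.  Input
    volumes are never mutated; all outputs go to ``out_dir``.
    """
    if isinstance(manifests, (str, Path)):
        manifests = volume_io.read_manifest(manifests)
    loaded: dict[str, list[VoxelGrid]] = {}
    for m in manifests:
        if volumes is not None and m.pot_id in volumes:
            grids = volumes[m.pot_id]
        else:
            grids = []
            for t, path in m.entries:
                if not Path(path).exists():
                    raise FileNotFoundError(
                        f"volume file missing for pot {m.pot_id} at day {t}: {path}")
                g = read_volume(path)
                g.pot_id, g.timepoint_days = m.pot_id, t
                grids.append(g)
        norm = []
        for g in grids:
            if not g.normalized:
                g = normalize_intensity(g, mode=config.normalization_mode,
                                        air_target=config.air_target)
            norm.append(g)
        loaded[m.pot_id] = norm

    first = loaded[manifests[0].pot_id][0]
    params = resolve_params(first, config.segmentation)
    calibration = _resolve_calibration(config)

    pots = []
    for m in manifests:
        try:
            pots.append(analyze_pot(loaded[m.pot_id], config, params, calibration,
                                    condition=m.condition))
        except Exception as exc:
            raise RuntimeError(f"pipeline failed for pot {m.pot_id}: {exc}") from exc
    conditions = {m.pot_id: m.condition for m in manifests}
    group = group_summary([p.curves for p in pots], conditions)
    result = RunResult(pots=pots, params=params, calibration=calibration, group=group)
    if out_dir is not None:
        _write_outputs(result, config, Path(out_dir), write_labels=write_labels)
    return result


def _write_outputs(result: RunResult, config: RunConfig, out_dir: Path, write_labels: bool) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    save_config(config, out_dir / "run_config.yaml")
    frozen = dataclasses.asdict(result.params)
    with open(out_dir / "frozen_params.json", "w") as fh:
        json.dump(frozen, fh, indent=1)
    objects = pd.concat(
        [records_to_dataframe([r for recs in p.records_by_timepoint for r in recs])
         for p in result.pots], ignore_index=True)
    objects.to_csv(out_dir / "objects.csv", index=False)
    tracks = pd.concat([tracks_to_dataframe(p.tracks) for p in result.pots], ignore_index=True)
    tracks.to_csv(out_dir / "tracks.csv", index=False)
    pd.concat([p.curves.per_tuber for p in result.pots], ignore_index=True).to_csv(
        out_dir / "growth_curves.csv", index=False)
    pd.concat([p.curves.plant_totals for p in result.pots], ignore_index=True).to_csv(
        out_dir / "plant_totals.csv", index=False)
    pd.concat([p.curves.velocity for p in result.pots], ignore_index=True).to_csv(
        out_dir / "velocity.csv", index=False)
    result.group.to_csv(out_dir / "group_summary.csv", index=False)
    if result.calibration is not None:
        with open(out_dir / "calibration.json", "w") as fh:
            json.dump(dataclasses.asdict(result.calibration), fh, indent=1)
    if write_labels:
        lab_dir = out_dir / "labels"
        lab_dir.mkdir(exist_ok=True)
        for p in result.pots:
            for lg in p.labels_by_timepoint:
                grid = VoxelGrid(lg.labels.astype(np.float32), lg.voxel_size_mm,
                                 origin_mm=lg.origin_mm, normalized=True,
                                 timepoint_days=lg.timepoint_days, pot_id=lg.pot_id)
                write_volume(grid, lab_dir / f"{p.pot_id}_d{lg.timepoint_days:05.1f}.mhd")
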