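"""Fresh-weight calibration and growth analytics.

The reconstructed linear absorption coefficient is proportional to
physical density for material of fixed elemental composition; tuber
tissue is essentially water plus hydrocarbons, so ``volume x mean
absorption`` is a *virtual fresh weight* proportional to true fresh
weight.  An ordinary-least-squares fit against a set of harvested,
weighed tubers calibrates it to grams; the fitted line is then applied
to every tracked tuber at every timepoint, giving growth curves,
per-plant totals ("the sum of all tuber weights"), and growth
velocities in g/day.

Sampling is irregular (a few scans per week), so velocities use divided
differences over the actual day spacings: second-order central
differences at interior timepoints, one-sided at the ends.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .features import CLASS_TUBER, ObjectRecord
from .tracking import TuberTrack

log = logging.getLogger(__name__)

__all__ = [
    "CalibrationModel", "GrowthCurve",
    "virtual_fresh_weight", "fit_calibration", "apply_calibration",
    "plant_totals_and_velocity", "group_summary",
]


@dataclass(frozen=True)
class CalibrationModel:
    """Linear map from virtual fresh weight to mass in grams."""

    slope: float           # g per (mm^3 x absorption unit)
    intercept: float       # g
    r_squared: float
    n_points: int
    residual_sd: float
    through_origin: bool = False

    def predict(self, vfw) -> np.ndarray:
        return self.slope * np.asarray(vfw, dtype=float) + self.intercept


@dataclass
class GrowthCurve:
    """Per-tuber, per-plant, and per-group growth summaries."""

    per_tuber: pd.DataFrame     # pot_id, track_id, timepoint_days, volume_mm3, vfw, fresh_weight_g
    plant_totals: pd.DataFrame  # pot_id, timepoint_days, total_g
    velocity: pd.DataFrame      # pot_id, timepoint_days, velocity_g_per_day


def virtual_fresh_weight(record: ObjectRecord) -> float:
    """``vfw = volume_mm3 x mean_absorption`` (uncalibrated units)."""
    if record.object_class != CLASS_TUBER:
        raise ValueError(f"virtual fresh weight is defined for tubers, got class {record.object_class!r}")
    return float(record.volume_mm3 * record.mean_absorption)


def fit_calibration(vfw, measured_mass_g, through_origin: bool = False) -> CalibrationModel:
    """OLS of measured mass on virtual fresh weight."""
    x = np.asarray(vfw, dtype=float)
    y = np.asarray(measured_mass_g, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("vfw and measured_mass_g must be aligned 1D sequences")
    n = x.size
    if n < 3:
        raise ValueError(f"calibration needs at least 3 points, got {n}")
    if np.ptp(x) == 0:
        raise ValueError("degenerate calibration input: all virtual fresh weights are equal")
    if through_origin:
        slope = float(x @ y / (x @ x))
        intercept = 0.0
        dof = n - 1
    else:
        fit = stats.linregress(x, y)
        slope, intercept = float(fit.slope), float(fit.intercept)
        dof = n - 2
    resid = y - (slope * x + intercept)
    ss_res = float(resid @ resid)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return CalibrationModel(slope=slope, intercept=intercept, r_squared=r2,
                            n_points=n, residual_sd=float(np.sqrt(ss_res / max(dof, 1))),
                            through_origin=through_origin)


def apply_calibration(model: CalibrationModel, records: list[ObjectRecord]) -> list[ObjectRecord]:
    """Attach ``fresh_weight_g`` to tuber records; negative predictions clamp to 0."""
    n_clamped = 0
    for rec in records:
        if rec.object_class != CLASS_TUBER:
            continue
        fw = float(model.predict(virtual_fresh_weight(rec)))
        if fw < 0:
            fw = 0.0
            n_clamped += 1
        rec.fresh_weight_g = fw
    if n_clamped:
        log.warning("apply_calibration: clamped %d negative fresh-weight predictions to 0", n_clamped)
    return records


def _velocity(times: np.ndarray, totals: np.ndarray) -> np.ndarray:
    # np.gradient on nonuniform spacing: second-order central differences at
    # interior points, one-sided at the ends
    if times.size < 2:
        return np.array([])
    return np.gradient(totals, times)


def plant_totals_and_velocity(
    tracks: list[TuberTrack], weight_field: str = "fresh_weight_g"
) -> GrowthCurve:
    """Per-tuber curves, per-plant totals, and growth velocity for one pot.

    Totals at each timepoint are exactly the sum of the member tubers'
    weights at that timepoint; tubers simply absent at a timepoint (not
    yet initiated, or a tracking gap) contribute nothing there.
    """
    tuber_tracks = [t for t in tracks if t.status == CLASS_TUBER]
    pots = {t.pot_id for t in tracks}
    if len(pots) > 1:
        raise ValueError(f"all tracks must share one pot_id, got {sorted(pots)}")
    rows = []
    for tr in tuber_tracks:
        for rec in tr.records:
            vfw = virtual_fresh_weight(rec)
            fw = getattr(rec, weight_field, None) if weight_field != "vfw" else vfw
            rows.append({
                "pot_id": tr.pot_id, "track_id": tr.track_id,
                "timepoint_days": rec.timepoint_days,
                "volume_mm3": rec.volume_mm3, "vfw": vfw,
                "fresh_weight_g": fw if fw is not None else np.nan,
            })
    per_tuber = pd.DataFrame(rows, columns=["pot_id", "track_id", "timepoint_days",
                                            "volume_mm3", "vfw", "fresh_weight_g"])
    if per_tuber.empty:
        empty_tot = pd.DataFrame(columns=["pot_id", "timepoint_days", "total_g"])
        empty_vel = pd.DataFrame(columns=["pot_id", "timepoint_days", "velocity_g_per_day"])
        return GrowthCurve(per_tuber, empty_tot, empty_vel)
    totals = (per_tuber.groupby(["pot_id", "timepoint_days"], as_index=False)["fresh_weight_g"]
              .sum().rename(columns={"fresh_weight_g": "total_g"}))
    vel_frames = []
    for pot_id, sub in totals.groupby("pot_id"):
        sub = sub.sort_values("timepoint_days")
        t = sub["timepoint_days"].to_numpy(float)
        v = _velocity(t, sub["total_g"].to_numpy(float))
        if v.size:
            vel_frames.append(pd.DataFrame({
                "pot_id": pot_id, "timepoint_days": t, "velocity_g_per_day": v}))
    velocity = (pd.concat(vel_frames, ignore_index=True) if vel_frames
                else pd.DataFrame(columns=["pot_id", "timepoint_days", "velocity_g_per_day"]))
    return GrowthCurve(per_tuber, totals, velocity)


def group_summary(curves: list[GrowthCurve], conditions: dict[str, str]) -> pd.DataFrame:
    """Mean +/- sd of plant totals and velocities across pots of each condition.

    Statistics are computed only at timepoints shared by every pot of the
    group; no temporal interpolation across pots is attempted.
    """
    totals = pd.concat([c.plant_totals for c in curves], ignore_index=True)
    velocity = pd.concat([c.velocity for c in curves], ignore_index=True)
    if totals.empty:
        return pd.DataFrame(columns=["condition", "timepoint_days", "n_pots",
                                     "mean_total_g", "sd_total_g",
                                     "mean_velocity_g_per_day", "sd_velocity_g_per_day"])
    totals = totals.assign(condition=totals["pot_id"].map(conditions))
    velocity = velocity.assign(condition=velocity["pot_id"].map(conditions))
    out = []
    for condition, sub in totals.groupby("condition"):
        pots = sub["pot_id"].unique()
        shared = None
        for p in pots:
            ts = set(sub.loc[sub["pot_id"] == p, "timepoint_days"])
            shared = ts if shared is None else shared & ts
        sub = sub[sub["timepoint_days"].isin(shared)]
        vel = velocity[(velocity["condition"] == condition)
                       & velocity["timepoint_days"].isin(shared)]
        g = sub.groupby("timepoint_days")["total_g"]
        gv = vel.groupby("timepoint_days")["velocity_g_per_day"]
        frame = pd.DataFrame({
            "condition": condition,
            "timepoint_days": sorted(shared),
            "n_pots": len(pots),
            "mean_total_g": g.mean().reindex(sorted(shared)).to_numpy(),
            "sd_total_g": g.std(ddof=1).reindex(sorted(shared)).to_numpy(),
            "mean_velocity_g_per_day": gv.mean().reindex(sorted(shared)).to_numpy(),
            "sd_velocity_g_per_day": gv.std(ddof=1).reindex(sorted(shared)).to_numpy(),
        })
        out.append(frame)
    return pd.concat(out, ignore_index=True)
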