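"""Linking segmented objects across timepoints into per-tuber tracks.

Tubers barely move between scans, so tracking compares each object's
center of mass with the positions seen at the previous timepoint and
greedily links nearest pairs first.  The admissible displacement is the
diameter of the sphere with the previous object's volume — a
size-dependent (hence time-dependent, since tubers grow) threshold that
scales naturally from millimeter-scale initials to mature tubers.

A track tolerates a configurable number of consecutive missed
observations (segmentation dropout at small sizes) before it terminates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .features import CLASS_CANDIDATE, ObjectRecord

log = logging.getLogger(__name__)

__all__ = ["TuberTrack", "sphere_equivalent_diameter", "link_timepoints", "build_tracks",
           "tracks_to_dataframe"]


@dataclass
class TuberTrack:
    """One physical object's time-ordered observations."""

    pot_id: str
    track_id: int
    records: list[ObjectRecord] = field(default_factory=list)
    matched_distance_mm: list[float] = field(default_factory=list)  # nan for the first record
    gaps: list[tuple[float, float]] = field(default_factory=list)   # (t_before, t_after) of missed obs
    status: str = CLASS_CANDIDATE

    @property
    def timepoints_days(self) -> list[float]:
        return [r.timepoint_days for r in self.records]

    @property
    def volumes_mm3(self) -> np.ndarray:
        return np.array([r.volume_mm3 for r in self.records])


def sphere_equivalent_diameter(volume_mm3: float) -> float:
    """Diameter of the sphere with the given volume, ``d = (6 V / pi)^(1/3)``."""
    if not volume_mm3 > 0:
        raise ValueError(f"volume must be positive, got {volume_mm3}")
    return float((6.0 * volume_mm3 / np.pi) ** (1.0 / 3.0))


def _greedy_match(
    prev: list[ObjectRecord], curr: list[ObjectRecord]
) -> list[tuple[int, int, float]]:
    """Greedy one-to-one matching in ascending centroid-distance order.

    A pair is admissible iff the displacement does not exceed the
    sphere-equivalent diameter of the *previous* object (whose identity
    is already established).  Ties break on (distance, prev index, curr
    label) for determinism.
    """
    pairs = []
    for i, p in enumerate(prev):
        thr = sphere_equivalent_diameter(p.volume_mm3)
        for j, c in enumerate(curr):
            d = float(np.linalg.norm(c.centroid_mm - p.centroid_mm))
            if d <= thr:
                pairs.append((d, i, c.label, j))
    pairs.sort()
    used_p, used_c, out = set(), set(), []
    for d, i, _, j in pairs:
        if i in used_p or j in used_c:
            continue
        used_p.add(i)
        used_c.add(j)
        out.append((i, j, d))
    return out


def link_timepoints(
    prev: list[ObjectRecord], curr: list[ObjectRecord]
) -> dict:
    """Match two consecutive timepoints' object lists.

    Returns ``{"matches": [(prev_idx, curr_idx, distance_mm)],
    "new": [curr_idx...], "lost": [prev_idx...]}``.
    """
    if prev and curr:
        tp = {r.timepoint_days for r in prev}
        tc = {r.timepoint_days for r in curr}
        if len(tp) > 1 or len(tc) > 1:
            raise ValueError("each list must come from a single timepoint")
        if tp == tc:
            raise ValueError("prev and curr lists are from the same timepoint")
        if max(tp) > min(tc):
            raise ValueError("curr timepoint must follow prev timepoint")
    matches = _greedy_match(prev, curr)
    mp = {i for i, _, _ in matches}
    mc = {j for _, j, _ in matches}
    return {
        "matches": matches,
        "new": [j for j in range(len(curr)) if j not in mc],
        "lost": [i for i in range(len(prev)) if i not in mp],
    }


def build_tracks(
    per_timepoint_records: list[list[ObjectRecord]],
    max_gap: int = 1,
    candidate_only: bool = True,
) -> list[TuberTrack]:
    """Sequentially link all timepoints of one pot into tracks.

    Records still classified as candidates are tracked (rejected stones
    and stolon fragments are left out unless ``candidate_only=False``).
    Track ids are assigned in creation order (timepoint, then label), so
    re-running on identical input reproduces identical tracks; within-
    timepoint record order does not matter.
    """
    if len(per_timepoint_records) < 2:
        raise ValueError("need at least 2 timepoints to build tracks")
    times = []
    for recs in per_timepoint_records:
        ts = {r.timepoint_days for r in recs}
        if len(ts) > 1:
            raise ValueError("mixed timepoints within one record list")
        times.append(next(iter(ts)) if ts else None)
    known = [t for t in times if t is not None]
    if any(b <= a for a, b in zip(known, known[1:])):
        raise ValueError("timepoints must be strictly increasing")

    tracks: list[TuberTrack] = []
    active: list[dict] = []  # {"track": TuberTrack, "gap": int}
    next_id = 1
    prev_time = None
    for recs in per_timepoint_records:
        usable = [r for r in recs if (not candidate_only) or r.object_class == CLASS_CANDIDATE]
        usable = sorted(usable, key=lambda r: r.label)
        # match against each active track's last seen record; tracks carrying a
        # gap compare across it, so link_timepoints' same-timepoint guard does
        # not apply here
        lasts = [slot["track"].records[-1] for slot in active]
        matches = _greedy_match(lasts, usable)
        link = {
            "matches": matches,
            "new": [j for j in range(len(usable)) if j not in {j_ for _, j_, _ in matches}],
        }
        t_now = usable[0].timepoint_days if usable else prev_time
        matched_slots = set()
        for i, j, d in link["matches"]:
            slot = active[i]
            if slot["gap"] > 0:
                slot["track"].gaps.append((slot["track"].records[-1].timepoint_days, usable[j].timepoint_days))
            slot["track"].records.append(usable[j])
            slot["track"].matched_distance_mm.append(d)
            slot["gap"] = 0
            matched_slots.add(i)
        survivors = []
        for i, slot in enumerate(active):
            if i in matched_slots:
                survivors.append(slot)
            else:
                slot["gap"] += 1
                if slot["gap"] <= max_gap:
                    survivors.append(slot)
        active = survivors
        for j in link["new"]:
            track = TuberTrack(pot_id=usable[j].pot_id, track_id=next_id,
                               records=[usable[j]], matched_distance_mm=[float("nan")])
            next_id += 1
            tracks.append(track)
            active.append({"track": track, "gap": 0})
        if usable:
            prev_time = t_now
    return tracks


def tracks_to_dataframe(tracks: list[TuberTrack]) -> pd.DataFrame:
    rows = []
    for tr in tracks:
        for rec, dist in zip(tr.records, tr.matched_distance_mm):
            rows.append({
                "pot_id": tr.pot_id, "track_id": tr.track_id,
                "timepoint_days": rec.timepoint_days, "label": rec.label,
                "volume_mm3": rec.volume_mm3, "mean_absorption": rec.mean_absorption,
                "cz_mm": rec.centroid_mm[0], "cy_mm": rec.centroid_mm[1], "cx_mm": rec.centroid_mm[2],
                "a_mm": rec.axis_lengths_mm[0], "b_mm": rec.axis_lengths_mm[1],
                "c_mm": rec.axis_lengths_mm[2],
                "aspect_ratio": rec.aspect_ratio, "class": rec.object_class,
                "matched_distance_mm": dist,
                "status": tr.status,
            })
    return pd.DataFrame(rows)
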