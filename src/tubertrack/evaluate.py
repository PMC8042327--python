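"""Metrics of a phantom run against its analytic ground truth."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .features import CLASS_TUBER
from .grids import LabelGrid
from .phantom import GroundTruth
from .tracking import TuberTrack

__all__ = ["match_labels_to_truth", "detection_table", "evaluate_against_truth"]


def match_labels_to_truth(pred: LabelGrid, truth: LabelGrid, tuber_ids) -> pd.DataFrame:
    """Overlap of every predicted label with every true tuber.

    Returns one row per (true tuber, best predicted label) with Dice and
    the fraction of true voxels covered; a tuber with no overlapping
    prediction gets pred_label 0.
    """
    if pred.shape != truth.shape:
        raise ValueError("prediction and truth grids must be congruent")
    rows = []
    p = pred.labels
    t = truth.labels
    pred_counts = np.bincount(p.ravel())
    for tid in tuber_ids:
        tmask = t == tid
        n_true = int(tmask.sum())
        if n_true == 0:
            continue
        overlap = np.bincount(p[tmask])
        overlap[0] = 0
        best = int(overlap.argmax()) if overlap.size > 1 and overlap.max() > 0 else 0
        inter = int(overlap[best]) if best else 0
        dice = 2.0 * inter / (n_true + int(pred_counts[best])) if best else 0.0
        rows.append({
            "tuber_id": int(tid), "pred_label": best,
            "true_voxels": n_true, "intersection": inter,
            "coverage": inter / n_true, "dice": dice,
        })
    return pd.DataFrame(rows, columns=["tuber_id", "pred_label", "true_voxels",
                                       "intersection", "coverage", "dice"])


def detection_table(
    pred_by_timepoint: list[LabelGrid],
    truth: GroundTruth,
    coverage_threshold: float = 0.5,
) -> pd.DataFrame:
    """Per-tuber per-timepoint detection: covered >= threshold of the true voxels."""
    rows = []
    for pred, frame in zip(pred_by_timepoint, truth.frames):
        ids = frame.tubers["tuber_id"].tolist()
        m = match_labels_to_truth(pred, frame.labels, ids)
        m = m.assign(timepoint_days=pred.timepoint_days,
                     detected=m["coverage"] >= coverage_threshold)
        rows.append(m)
    return pd.concat(rows, ignore_index=True)


@dataclass
class EvaluationReport:
    detection_recall: float
    detection_precision: float
    mean_dice: float
    identity_accuracy: float
    volume_mean_rel_error: float
    per_tuber: pd.DataFrame

    def as_dict(self) -> dict:
        return {
            "detection_recall": self.detection_recall,
            "detection_precision": self.detection_precision,
            "mean_dice": self.mean_dice,
            "identity_accuracy": self.identity_accuracy,
            "volume_mean_rel_error": self.volume_mean_rel_error,
        }


def evaluate_against_truth(
    pred_by_timepoint: list[LabelGrid],
    tracks: list[TuberTrack],
    truth: GroundTruth,
    min_true_volume_mm3: float = 0.0,
    coverage_threshold: float = 0.5,
) -> EvaluationReport:
    """Detection, overlap, identity, and volume metrics for one pot's run.

    Recall counts true tubers (above the volume floor) covered by some
    predicted label; precision counts final tuber-class tracks whose
    records actually overlap a true tuber.  Identity accuracy is the
    fraction of accepted tracks that map to exactly one true tuber over
    their whole lifetime.
    """
    if len(pred_by_timepoint) != len(truth.frames):
        raise ValueError("prediction/truth timepoint count mismatch")
    table = detection_table(pred_by_timepoint, truth, coverage_threshold)
    table = table.merge(
        truth.tubers[["timepoint_days", "tuber_id", "true_volume_mm3"]],
        on=["timepoint_days", "tuber_id"], how="left")
    eligible = table[table["true_volume_mm3"] >= min_true_volume_mm3]
    recall = float(eligible["detected"].mean()) if len(eligible) else float("nan")
    mean_dice = float(eligible["dice"].mean()) if len(eligible) else float("nan")

    vol = eligible[eligible["detected"]].copy()
    if len(vol):
        pred_vox = []
        for _, row in vol.iterrows():
            idx = [g.timepoint_days for g in pred_by_timepoint].index(row["timepoint_days"])
            pred_vox.append(int((pred_by_timepoint[idx].labels == row["pred_label"]).sum())
                            * pred_by_timepoint[idx].voxel_volume_mm3)
        vol["pred_volume_mm3"] = pred_vox
        volume_err = float(np.mean(np.abs(vol["pred_volume_mm3"] - vol["true_volume_mm3"])
                                   / vol["true_volume_mm3"]))
    else:
        volume_err = float("nan")

    # map (timepoint, pred label) -> true tuber id
    lookup = {(row["timepoint_days"], row["pred_label"]): row["tuber_id"]
              for _, row in table.iterrows() if row["pred_label"] > 0}
    tuber_tracks = [t for t in tracks if t.status == CLASS_TUBER]
    n_pure = 0
    n_matched = 0
    for tr in tuber_tracks:
        ids = {lookup.get((rec.timepoint_days, rec.label)) for rec in tr.records}
        ids.discard(None)
        if ids:
            n_matched += 1
            if len(ids) == 1 and len(tr.records) == len([
                    rec for rec in tr.records
                    if lookup.get((rec.timepoint_days, rec.label)) is not None]):
                n_pure += 1
    precision = n_matched / len(tuber_tracks) if tuber_tracks else float("nan")
    identity = n_pure / len(tuber_tracks) if tuber_tracks else float("nan")
    return EvaluationReport(
        detection_recall=recall,
        detection_precision=precision,
        mean_dice=mean_dice,
        identity_accuracy=identity,
        volume_mean_rel_error=volume_err,
        per_tuber=table,
    )
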