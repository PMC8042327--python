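"""Benchmark studies of the pipeline against analytic phantom truth.

Two quantitative figures of merit of the method are recomputed here from
scratch on synthetic scenes:

* :func:`calibration_study` — fidelity of the virtual fresh weight
  (segmented volume x mean absorption) as a mass proxy: R^2 of an OLS of
  true mass against vfw over a cohort of spherical tubers of constant
  composition, segmented out of granular-soil volumes.
* :func:`detectability_study` — the smallest spherical tuber diameter
  segmented in every replicate at the scanner's reconstructed voxel size
  (88.9 um), scanning the 2-8 mm range in inhomogeneous soil.

Both run the *default* frozen segmentation parameter set, calibrated
once on the first rendered volume of each study.
"""

from __future__ import annotations

import logging

import numpy as np

from .evaluate import match_labels_to_truth
from .growth import fit_calibration
from .phantom import DENSITY_G_PER_MM3, render_scene, single_sphere_scene
from .segmentation import SegmentationParams, resolve_params, segment_volume

log = logging.getLogger(__name__)

__all__ = ["calibration_study", "detectability_study"]


def _child_seeds(seed: int, n: int) -> list[int]:
    rng = np.random.default_rng(seed)
    return [int(s) for s in rng.integers(0, 2**31 - 1, size=n)]


def calibration_study(
    seed: int = 0,
    n_tubers: int = 30,
    diameter_range_mm: tuple[float, float] = (4.0, 25.0),
    voxel_size_mm: float = 0.2,
    mult_noise_sd: float = 0.02,
    margin_vox: int = 20,
) -> dict:
    """Segment ``n_tubers`` spheres from soil and calibrate mass against vfw.

    Each sphere sits in its own cropped soil sub-volume sized to the
    tuber plus a fixed margin.  True mass is tissue density times the
    analytic sphere volume; vfw comes from the segmented label.  Returns
    the OLS R^2, slope, and per-tuber table.
    """
    diameters = np.linspace(*diameter_range_mm, n_tubers)
    seeds = _child_seeds(seed, n_tubers)
    params: SegmentationParams | None = None
    vfw, mass, rows = [], [], []
    for d, s in zip(diameters, seeds):
        n = int(np.ceil(d / voxel_size_mm)) + 2 * margin_vox
        scene = single_sphere_scene(d, voxel_size_mm=voxel_size_mm, shape_vox=(n, n, n),
                                    seed=s, noise_sigma=0.0, mult_noise_sd=mult_noise_sd)
        grid, truth = render_scene(scene, 0.0, normalized=True)
        if params is None:
            params = resolve_params(grid, SegmentationParams())
        labels = segment_volume(grid, params)
        m = match_labels_to_truth(labels, truth.labels, [1])
        row = m.iloc[0]
        if row["pred_label"] == 0:
            log.warning("calibration_study: %.2f mm tuber not segmented (seed %d)", d, s)
            continue
        seg_mask = labels.labels == row["pred_label"]
        seg_vol = float(seg_mask.sum()) * grid.voxel_volume_mm3
        mean_abs = float(np.asarray(grid.data)[seg_mask].mean())
        true_vol = float(truth.tubers["true_volume_mm3"].iloc[0])
        vfw.append(seg_vol * mean_abs)
        mass.append(DENSITY_G_PER_MM3 * true_vol)
        rows.append({"diameter_mm": float(d), "seg_volume_mm3": seg_vol,
                     "true_volume_mm3": true_vol, "mean_absorption": mean_abs,
                     "vfw": vfw[-1], "true_mass_g": mass[-1]})
    model = fit_calibration(vfw, mass)
    return {
        "r_squared": model.r_squared,
        "slope_g_per_unit": model.slope,
        "intercept_g": model.intercept,
        "n_segmented": len(vfw),
        "n_tubers": n_tubers,
        "tubers": rows,
    }


def detectability_study(
    seed: int = 0,
    diameters_mm=None,
    replicates: int = 10,
    voxel_size_mm: float = 0.0889,
    shape_vox: tuple[int, int, int] = (160, 160, 160),
    coverage_threshold: float = 0.5,
) -> dict:
    """Smallest sphere diameter detected in every replicate.

    A tuber counts as detected when one segmented label covers at least
    ``coverage_threshold`` of its true voxels.  The reported diameter is
    the smallest one detected in all replicates such that every larger
    probed diameter is fully detected as well.
    """
    if diameters_mm is None:
        # dense 0.4 mm steps through the decision region, thinned outside it
        diameters_mm = [2.4, 2.8, 3.2, 3.6, 4.0, 4.8, 6.4, 8.0]
    diameters_mm = np.asarray(sorted(diameters_mm), dtype=float)
    seeds = np.asarray(_child_seeds(seed, diameters_mm.size * replicates)).reshape(
        diameters_mm.size, replicates)
    params: SegmentationParams | None = None
    detected = np.zeros(seeds.shape, dtype=bool)
    for i, d in enumerate(diameters_mm):
        for j in range(replicates):
            scene = single_sphere_scene(float(d), voxel_size_mm=voxel_size_mm,
                                        shape_vox=shape_vox, seed=int(seeds[i, j]))
            grid, truth = render_scene(scene, 0.0, normalized=True)
            if params is None:
                params = resolve_params(grid, SegmentationParams())
            labels = segment_volume(grid, params)
            m = match_labels_to_truth(labels, truth.labels, [1])
            detected[i, j] = bool(len(m)) and m.iloc[0]["coverage"] >= coverage_threshold
        log.info("detectability: %.1f mm -> %d/%d detected", d, detected[i].sum(), replicates)
    full = detected.all(axis=1)
    # smallest diameter from which detection stays complete upward
    smallest = float("nan")
    for i in range(diameters_mm.size):
        if full[i:].all():
            smallest = float(diameters_mm[i])
            break
    return {
        "smallest_fully_detected_mm": smallest,
        "diameters_mm": [float(d) for d in diameters_mm],
        "n_detected": [int(n) for n in detected.sum(axis=1)],
        "replicates": replicates,
    }
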