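import dataclasses

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from tubertrack.grids import VoxelGrid
from tubertrack.phantom import SoilSpec, default_scene, render_scene
from tubertrack.segmentation import (SegmentationParams, ball, binarize, dilate, dilate_labels,
                                     erode, estimate_variance_threshold, label_components,
                                     local_variance, median_filter_3d, resolve_params,
                                     segment_volume)
from tubertrack.volume_io import normalize_intensity


def _grid(data, voxel=1.0, **kw):
    return VoxelGrid(np.asarray(data, dtype=float), voxel, **kw)


# ---------------------------------------------------------------------------
# brute-force oracles
# ---------------------------------------------------------------------------

def brute_force_median(data, z, y, x, r=1):
    vals = sorted(data[z - r:z + r + 1, y - r:y + r + 1, x - r:x + r + 1].ravel())
    return vals[len(vals) // 2]


def gaussian_kernel_1d(sigma, truncate=4.0):
    r = int(truncate * sigma + 0.5)
    i = np.arange(-r, r + 1, dtype=float)
    w = np.exp(-(i**2) / (2.0 * sigma**2))
    return w / w.sum()


def brute_force_local_variance(data, sigma, z, y, x):
    """Weighted second moment minus squared weighted first moment with an
    explicit truncated separable Gaussian window."""
    w1 = gaussian_kernel_1d(sigma)
    r = len(w1) // 2
    block = data[z - r:z + r + 1, y - r:y + r + 1, x - r:x + r + 1].astype(float)
    w = w1[:, None, None] * w1[None, :, None] * w1[None, None, :]
    m1 = float((w * block).sum())
    m2 = float((w * block**2).sum())
    return m2 - m1 * m1


def flood_fill_components(mask):
    """BFS 26-neighborhood labeling, independent of scipy."""
    labels = np.zeros(mask.shape, dtype=int)
    nxt = 0
    offsets = [(dz, dy, dx) for dz in (-1, 0, 1) for dy in (-1, 0, 1) for dx in (-1, 0, 1)
               if (dz, dy, dx) != (0, 0, 0)]
    for start in zip(*np.nonzero(mask)):
        if labels[start]:
            continue
        nxt += 1
        stack = [start]
        labels[start] = nxt
        while stack:
            z, y, x = stack.pop()
            for dz, dy, dx in offsets:
                n = (z + dz, y + dy, x + dx)
                if all(0 <= c < s for c, s in zip(n, mask.shape)) and mask[n] and not labels[n]:
                    labels[n] = nxt
                    stack.append(n)
    return labels, nxt


# ---------------------------------------------------------------------------
# median filter
# ---------------------------------------------------------------------------

def test_median_constant_grid_unchanged():
    grid = _grid(np.full((7, 7, 7), 3.5))
    np.testing.assert_array_equal(median_filter_3d(grid, 1).data, grid.data)


def test_median_removes_isolated_impulse():
    data = np.zeros((7, 7, 7))
    data[3, 3, 3] = 100.0
    assert median_filter_3d(_grid(data), 1).data.max() == 0.0


def test_median_matches_brute_force_on_random_grid():
    rng = np.random.default_rng(7)
    data = rng.normal(size=(9, 9, 9))
    out = median_filter_3d(_grid(data), 1).data
    for z, y, x in rng.integers(1, 8, size=(12, 3)):
        assert out[z, y, x] == pytest.approx(brute_force_median(data, z, y, x), abs=1e-12)


def test_median_requires_positive_radius():
    with pytest.raises(ValueError):
        median_filter_3d(_grid(np.zeros((3, 3, 3))), 0)


# ---------------------------------------------------------------------------
# local variance
# ---------------------------------------------------------------------------

def test_variance_of_constant_grid_is_zero():
    grid = _grid(np.full((16, 16, 16), 2.0), voxel=0.1)
    assert local_variance(grid, 0.3).data.max() == 0.0


def test_variance_of_white_noise_approaches_noise_variance():
    rng = np.random.default_rng(42)
    sigma_noise = 0.5
    grid = _grid(rng.normal(0, sigma_noise, size=(48, 48, 48)), voxel=1.0)
    v = local_variance(grid, 3.0).data  # window of 3 voxels >> voxel
    interior = v[14:-14, 14:-14, 14:-14]
    assert float(interior.mean()) == pytest.approx(sigma_noise**2, rel=0.10)


def test_variance_matches_brute_force_window_moments():
    rng = np.random.default_rng(11)
    data = rng.normal(1.0, 0.4, size=(40, 40, 40))
    sigma = 2.0
    out = local_variance(_grid(data, voxel=1.0), sigma).data
    margin = int(4.0 * sigma + 0.5) + 1
    for z, y, x in rng.integers(margin, 40 - margin, size=(10, 3)):
        expect = brute_force_local_variance(data, sigma, z, y, x)
        assert out[z, y, x] == pytest.approx(expect, rel=1e-6)


def test_unresolvable_window_fails():
    grid = _grid(np.zeros((8, 8, 8)), voxel=1.0)
    with pytest.raises(ValueError, match="unresolvable"):
        local_variance(grid, 0.3)


# ---------------------------------------------------------------------------
# binarize
# ---------------------------------------------------------------------------

def test_binarize_keeps_homogeneous_bright_and_drops_homogeneous_air():
    shape = (6, 6, 6)
    v = _grid(np.zeros(shape))
    bright = _grid(np.full(shape, 1.0))
    air = _grid(np.zeros(shape))
    assert binarize(v, bright, 0.01, 0.3).all()
    assert not binarize(v, air, 0.01, 0.3).any()


def test_binarize_rejects_nonfinite_thresholds():
    g = _grid(np.zeros((4, 4, 4)))
    with pytest.raises(ValueError):
        binarize(g, g, float("nan"), 0.3)


def test_binarize_separates_tuber_from_soil_on_phantom():
    """The tuber interior (away from the variance band at the edge) is almost
    fully kept while most soil is dropped."""
    from scipy import ndimage as ndi

    from tubertrack.phantom import LABEL_SOIL, single_sphere_scene
    scene = single_sphere_scene(10.0, voxel_size_mm=0.2, shape_vox=(90, 90, 90), seed=5)
    grid, truth = render_scene(scene, 0.0, normalized=True)
    params = resolve_params(grid, SegmentationParams())
    med = median_filter_3d(grid, params.median_radius_vox)
    mask = binarize(local_variance(med, params.lambda_mm), med,
                    params.variance_threshold, params.absorption_floor)
    tuber = truth.labels.labels == 1
    # the edge band extends ~ dilation-restoration depth into the object
    band = params.dilation_radius_for(grid.voxel_size_mm) - params.erosion_radius_vox
    interior = ndi.binary_erosion(tuber, iterations=band + 2)
    soil = truth.labels.labels == LABEL_SOIL
    assert mask[interior].mean() >= 0.90
    assert mask[soil].mean() <= 0.30  # "most of the surrounding soil" dropped


# ---------------------------------------------------------------------------
# morphology
# ---------------------------------------------------------------------------

def test_erosion_removes_object_smaller_than_element():
    mask = np.zeros((7, 7, 7), bool)
    mask[3, 3, 3] = True
    assert not erode(mask, 1).any()


def test_erode_then_dilate_restores_ball_volume():
    pad = np.pad(ball(10), 4)
    restored = dilate(erode(pad, 2), 2)
    assert abs(int(restored.sum()) - int(pad.sum())) / pad.sum() < 0.05


def test_erosion_disconnects_tangent_stolon():
    # ball of radius 8 with a tangent tube of radius 3: after erosion with
    # radius 4 no stolon voxel remains attached to the tuber core
    zz, yy, xx = np.mgrid[:40, :40, :60]
    tuber = (zz - 20) ** 2 + (yy - 20) ** 2 + (xx - 20) ** 2 <= 8**2
    tube = ((zz - 20) ** 2 + (yy - 20) ** 2 <= 3**2) & (xx >= 26) & (xx < 55)
    mask = tuber | tube
    before = label_components(mask)
    assert len(before.label_ids) == 1
    after = erode(mask, 4)
    eroded_labels = label_components(after)
    assert len(eroded_labels.label_ids) >= 1
    assert not (after & tube & ~tuber).any()  # stolon voxels gone or disconnected


@given(st.integers(0, 1000))
def test_erosion_never_creates_foreground(seed):
    rng = np.random.default_rng(seed)
    mask = rng.random((12, 12, 12)) > 0.6
    assert not (erode(mask, 1) & ~mask).any()


# ---------------------------------------------------------------------------
# connected components
# ---------------------------------------------------------------------------

def test_corner_sharing_voxels_are_one_component():
    mask = np.zeros((4, 4, 4), bool)
    mask[0, 0, 0] = mask[1, 1, 1] = True
    assert len(label_components(mask).label_ids) == 1


def test_separated_voxels_are_two_components():
    mask = np.zeros((5, 5, 5), bool)
    mask[0, 0, 0] = mask[0, 0, 2] = True
    assert len(label_components(mask).label_ids) == 2


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_labeling_matches_flood_fill_oracle(seed):
    rng = np.random.default_rng(seed)
    mask = rng.random((12, 12, 12)) > 0.7
    got = label_components(mask).labels
    want, n = flood_fill_components(mask)
    assert (got > 0).sum() == (want > 0).sum()
    assert len(np.unique(got)) - 1 == n
    # identical partitions up to relabeling: the label pairing is a bijection
    pairs = {(int(a), int(b)) for a, b in zip(want[mask], got[mask])}
    assert len(pairs) == n
    assert len({a for a, _ in pairs}) == n and len({b for _, b in pairs}) == n


def test_small_components_removed_and_labels_dense_by_size():
    mask = np.zeros((12, 12, 12), bool)
    mask[1:5, 1:5, 1:5] = True     # 64 voxels
    mask[8:10, 8:10, 8:10] = True  # 8 voxels
    mask[11, 11, 11] = True        # 1 voxel
    lab = label_components(mask, voxel_size_mm=1.0, min_object_volume_mm3=2.0)
    ids = lab.label_ids
    assert list(ids) == [1, 2]
    assert (lab.labels == 1).sum() == 64
    assert (lab.labels == 2).sum() == 8


def test_constrained_dilation_never_merges_labels():
    lab = np.zeros((9, 9, 9), np.int32)
    lab[4, 4, 2] = 1
    lab[4, 4, 6] = 2
    from tubertrack.grids import LabelGrid
    out = dilate_labels(LabelGrid(lab, 1.0), 3)
    assert (out.labels[lab > 0] == lab[lab > 0]).all()
    grown1 = out.labels == 1
    grown2 = out.labels == 2
    assert grown1.sum() > 1 and grown2.sum() > 1
    # contested middle plane went to the lower label
    assert out.labels[4, 4, 4] == 1


# ---------------------------------------------------------------------------
# composed pipeline
# ---------------------------------------------------------------------------

def test_soil_only_phantom_yields_no_tubers():
    """Low-variance pockets of pure soil may survive segmentation, but none
    survives the absorption/aspect/growth classification as a tuber."""
    from tubertrack.phantom import render_series
    from tubertrack.pipeline import RunConfig, analyze_pot
    from tubertrack.segmentation import estimate_variance_threshold

    scene = default_scene(seed=5, timepoints_days=[1.0, 5.0, 8.0, 12.0])
    scene = dataclasses.replace(scene, tubers=[], stolons=[], stones=[])
    _, grids, _ = render_series(scene)
    norm = [normalize_intensity(g) for g in grids]
    params = resolve_params(norm[0], SegmentationParams())
    config = RunConfig()
    pot = analyze_pot(norm, config, params, calibration=None)
    assert all(t.status != "tuber" for t in pot.tracks)
    assert pot.curves.per_tuber.empty


def test_segmentation_is_deterministic(default_run):
    # re-segment the first volume of the stock experiment with the frozen set
    spec = default_run["specs"][0]
    grid, _ = render_scene(spec, spec.timepoints_days[0])
    gn = normalize_intensity(grid)
    params = default_run["result"].params
    a = segment_volume(gn, params)
    b = segment_volume(gn, params)
    np.testing.assert_array_equal(a.labels, b.labels)


def test_unnormalized_volume_rejected():
    grid = _grid(np.ones((8, 8, 8)), voxel=0.4)
    with pytest.raises(ValueError, match="normalized"):
        segment_volume(grid, SegmentationParams(variance_threshold=0.1))


def test_default_phantom_tubers_recovered_with_high_dice(default_run):
    """Each true tuber of the stock 3-tuber pot matches a distinct label with Dice >= 0.85."""
    from tubertrack.evaluate import match_labels_to_truth
    result = default_run["result"]
    for pot in result.pots:
        truth = default_run["truths"][pot.pot_id]
        m = match_labels_to_truth(pot.labels_by_timepoint[-1], truth.frames[-1].labels, [1, 2, 3])
        assert (m["dice"] >= 0.85).all()
        assert m["pred_label"].nunique() == 3


def test_segmented_volume_within_ten_percent_for_mid_sized_tubers(default_run):
    """Restored label volumes track analytic volumes within 10% (tubers >= 5 mm)."""
    from tubertrack.evaluate import evaluate_against_truth
    for pot in default_run["result"].pots:
        rep = evaluate_against_truth(pot.labels_by_timepoint, pot.tracks,
                                     default_run["truths"][pot.pot_id],
                                     min_true_volume_mm3=65.0)  # d >= 5 mm
        assert rep.volume_mean_rel_error < 0.10
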