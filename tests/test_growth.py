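import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from conftest import make_record
from tubertrack.features import CLASS_TUBER
from tubertrack.growth import (apply_calibration, fit_calibration, group_summary,
                               plant_totals_and_velocity, virtual_fresh_weight)
from tubertrack.phantom import DENSITY_G_PER_MM3, GrowthModel
from tubertrack.tracking import TuberTrack


def _tuber_record(volume, absorption=1.0, t=0.0, **kw):
    return make_record(t=t, volume=volume, absorption=absorption, cls=CLASS_TUBER, **kw)


def test_virtual_fresh_weight_is_volume_times_absorption():
    assert virtual_fresh_weight(_tuber_record(100.0, 1.0)) == pytest.approx(100.0)


@given(st.floats(1.0, 1e5), st.floats(0.5, 2.0))
def test_virtual_fresh_weight_linear_in_volume(v, a):
    one = virtual_fresh_weight(_tuber_record(v, a))
    two = virtual_fresh_weight(_tuber_record(2 * v, a))
    assert two == pytest.approx(2 * one, rel=1e-12)


def test_vfw_requires_tuber_class():
    with pytest.raises(ValueError):
        virtual_fresh_weight(make_record(cls="candidate"))


def test_vfw_tracks_true_mass_at_zero_noise():
    """30 noiseless constant-composition tubers: vfw ~ mass, r >= 0.999."""
    volumes = np.linspace(50, 8000, 30)
    vfw = [virtual_fresh_weight(_tuber_record(v, 1.0)) for v in volumes]
    mass = DENSITY_G_PER_MM3 * volumes
    r = np.corrcoef(vfw, mass)[0, 1]
    assert r >= 0.999


# ---------------------------------------------------------------------------
# calibration
# ---------------------------------------------------------------------------

def test_perfect_line_gives_unit_r_squared():
    x = np.linspace(10, 100, 10)
    model = fit_calibration(x, 0.002 * x + 0.5)
    assert model.r_squared == pytest.approx(1.0)
    assert model.slope == pytest.approx(0.002)
    assert model.intercept == pytest.approx(0.5)


def test_noisy_cohort_keeps_r_squared_above_paper_value():
    """2% multiplicative noise on 30 tubers leaves R^2 >= 0.99."""
    rng = np.random.default_rng(8)
    volumes = np.linspace(34, 8200, 30)  # ~4 to 25 mm diameter spheres
    mass = DENSITY_G_PER_MM3 * volumes
    vfw = volumes * 1.0 * (1 + 0.02 * rng.standard_normal(30))
    model = fit_calibration(vfw, mass)
    assert model.r_squared >= 0.99


def test_density_slope_recovered_within_three_percent():
    rng = np.random.default_rng(5)
    volumes = np.linspace(34, 8200, 30)
    vfw = volumes * (1 + 0.01 * rng.standard_normal(30))
    model = fit_calibration(vfw, DENSITY_G_PER_MM3 * volumes)
    assert model.slope == pytest.approx(DENSITY_G_PER_MM3, rel=0.03)


def test_degenerate_calibration_fails():
    with pytest.raises(ValueError, match="degenerate"):
        fit_calibration([5.0, 5.0, 5.0], [1.0, 2.0, 3.0])
    with pytest.raises(ValueError):
        fit_calibration([1.0, 2.0], [1.0, 2.0])


def test_through_origin_fit_has_zero_intercept():
    x = np.linspace(10, 100, 10)
    model = fit_calibration(x, 0.002 * x, through_origin=True)
    assert model.intercept == 0.0
    assert model.slope == pytest.approx(0.002)


def test_calibration_centroid_property():
    """Predicting at the mean vfw returns the mean measured mass (OLS identity)."""
    rng = np.random.default_rng(2)
    x = rng.uniform(10, 500, 20)
    y = 0.001 * x + rng.normal(0, 0.01, 20)
    model = fit_calibration(x, y)
    assert float(model.predict(x.mean())) == pytest.approx(float(y.mean()), abs=1e-12)


def test_apply_calibration_clamps_negative_predictions():
    from tubertrack.growth import CalibrationModel
    model = CalibrationModel(slope=0.001, intercept=-1.0, r_squared=1.0,
                             n_points=3, residual_sd=0.0)
    rec = _tuber_record(100.0)
    apply_calibration(model, [rec])
    assert rec.fresh_weight_g == 0.0
    zero = CalibrationModel(slope=0.001, intercept=0.0, r_squared=1.0,
                            n_points=3, residual_sd=0.0)
    rec2 = _tuber_record(1e-9)
    rec2.volume_mm3 = 1e-9
    apply_calibration(zero, [rec2])
    assert rec2.fresh_weight_g == pytest.approx(0.0, abs=1e-10)


# ---------------------------------------------------------------------------
# totals and velocity
# ---------------------------------------------------------------------------

def _tuber_track(track_id, times, volumes, pot="p1"):
    recs = [_tuber_record(v, t=t, label=track_id, pot_id=pot) for t, v in zip(times, volumes)]
    for r in recs:
        r.fresh_weight_g = DENSITY_G_PER_MM3 * r.volume_mm3
    tr = TuberTrack(pot_id=pot, track_id=track_id, records=recs,
                    matched_distance_mm=[float("nan")] * len(recs))
    tr.status = CLASS_TUBER
    return tr


def test_totals_are_sum_of_member_weights():
    t1 = _tuber_track(1, [0.0], [3.0 / DENSITY_G_PER_MM3])
    t2 = _tuber_track(2, [0.0], [4.0 / DENSITY_G_PER_MM3])
    curves = plant_totals_and_velocity([t1, t2])
    assert curves.plant_totals["total_g"].iloc[0] == pytest.approx(7.0)
    # conservation is exact, not approximate
    assert curves.plant_totals["total_g"].iloc[0] == curves.per_tuber["fresh_weight_g"].sum()


def test_linear_total_gives_constant_velocity():
    times = [0.0, 2.0, 4.0, 6.0, 8.0]
    volumes = [(1.0 + 0.5 * t) / DENSITY_G_PER_MM3 for t in times]
    curves = plant_totals_and_velocity([_tuber_track(1, times, volumes)])
    np.testing.assert_allclose(curves.velocity["velocity_g_per_day"], 0.5, rtol=1e-9)


def test_velocity_handles_irregular_sampling():
    times = [1.0, 4.0, 5.0, 9.0, 10.0]
    masses = [2.0 * t for t in times]  # exactly linear in actual days
    volumes = [m / DENSITY_G_PER_MM3 for m in masses]
    curves = plant_totals_and_velocity([_tuber_track(1, times, volumes)])
    np.testing.assert_allclose(curves.velocity["velocity_g_per_day"], 2.0, rtol=1e-9)


def test_velocity_integrates_back_to_total_change():
    gm = GrowthModel(initial_volume_mm3=150.0, rate_per_day=0.15, capacity_mm3=3000.0)
    times = np.arange(1.0, 42.0, 2.0)
    volumes = [gm.volume_mm3(t) for t in times]
    curves = plant_totals_and_velocity([_tuber_track(1, times, volumes)])
    totals = curves.plant_totals.sort_values("timepoint_days")["total_g"].to_numpy()
    vel = curves.velocity.sort_values("timepoint_days")["velocity_g_per_day"].to_numpy()
    integral = np.trapezoid(vel, times)
    assert integral == pytest.approx(totals[-1] - totals[0], rel=0.05)


def test_single_timepoint_yields_totals_but_no_velocity():
    curves = plant_totals_and_velocity([_tuber_track(1, [3.0], [500.0])])
    assert len(curves.plant_totals) == 1
    assert curves.velocity.empty


def test_mixed_pots_rejected():
    a = _tuber_track(1, [0.0], [100.0], pot="p1")
    b = _tuber_track(2, [0.0], [100.0], pot="p2")
    with pytest.raises(ValueError):
        plant_totals_and_velocity([a, b])


def test_group_summary_uses_shared_timepoints_only():
    c1 = plant_totals_and_velocity([_tuber_track(1, [0.0, 2.0, 4.0], [100, 200, 300], pot="a")])
    c2 = plant_totals_and_velocity([_tuber_track(1, [0.0, 2.0], [100, 200], pot="b")])
    out = group_summary([c1, c2], {"a": "control", "b": "control"})
    assert sorted(out["timepoint_days"]) == [0.0, 2.0]
    assert (out["n_pots"] == 2).all()
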