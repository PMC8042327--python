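import dataclasses

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from tubertrack.features import ObjectRecord
from tubertrack.phantom import (DENSITY_G_PER_MM3, GrowthModel, PotSpec, SceneSpec, SoilSpec,
                                TuberSpec, default_experiment, render_series)
from tubertrack.pipeline import RunConfig, run_pipeline

settings.register_profile(
    "suite", derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow], deadline=None)
settings.load_profile("suite")


def make_record(pot_id="p", t=0.0, label=1, volume=100.0, absorption=1.0,
                centroid=(0.0, 0.0, 0.0), axes=(3.0, 3.0, 3.0), cls="candidate"):
    axes = tuple(sorted(axes, reverse=True))
    return ObjectRecord(
        pot_id=pot_id, timepoint_days=t, label=label, volume_mm3=volume,
        mean_absorption=absorption, centroid_mm=np.asarray(centroid, float),
        axis_lengths_mm=np.asarray(axes, float), aspect_ratio=axes[0] / axes[-1],
        object_class=cls)


@pytest.fixture
def record_factory():
    return make_record


def tiny_scene(seed=0, condition="control"):
    """A fast 64^3 two-tuber pot for I/O and CLI round trips."""
    pot = PotSpec(center_yx_mm=(16.0, 16.0), inner_radius_mm=13.0, wall_thickness_mm=1.0,
                  bottom_mm=2.0, soil_top_mm=26.0, wall_top_mm=29.0)
    growth = dict(initial_volume_mm3=268.0, rate_per_day=0.15, capacity_mm3=900.0)
    tubers = [
        TuberSpec(center_mm=(12.0, 11.0, 16.0), semi_axes_mm=(4.0, 4.0, 4.0),
                  growth=GrowthModel(**growth)),
        TuberSpec(center_mm=(18.0, 21.0, 16.0), semi_axes_mm=(4.0, 4.0, 4.0),
                  growth=GrowthModel(**growth)),
    ]
    return SceneSpec(shape_vox=(64, 64, 64), voxel_size_mm=0.5,
                     soil=SoilSpec(), tubers=tubers, pot=pot,
                     timepoints_days=[1.0, 4.0, 7.0, 10.0],
                     pot_id=f"tiny-{condition}", condition=condition, seed=seed)


@pytest.fixture
def tiny_scene_factory():
    return tiny_scene


@pytest.fixture(scope="session")
def default_run():
    """One frozen parameter set applied to the whole control+stress experiment."""
    specs = default_experiment(seed=2)
    manifests, volumes, truths = [], {}, {}
    for spec in specs:
        m, grids, truth = render_series(spec)
        manifests.append(m)
        volumes[spec.pot_id] = grids
        truths[spec.pot_id] = truth
    config = RunConfig(stress_window=(15.0, 29.0), calibration_slope=DENSITY_G_PER_MM3)
    result = run_pipeline(config, manifests, volumes=volumes)
    return {"specs": specs, "result": result, "truths": truths, "config": config}
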