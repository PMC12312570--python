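import dataclasses

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from mfstretch.aggregate_sim import (
    CylinderGeometry,
    ExperimentConfig,
    render_frames,
    simulate_experiment,
)
from mfstretch.calibration import CantileverCalibration
from mfstretch.springmodel import CellModel
from mfstretch.tracking import GeometryMeasurement

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def cell():
    """Study-condition cell: r_c = 3.3 um, k_c = 8e-4 N/m."""
    return CellModel()


@pytest.fixture(scope="session")
def base_config():
    return ExperimentConfig(seed=1)


@pytest.fixture(scope="session")
def reference_geometry():
    return CylinderGeometry(R0=30e-6, L0=60e-6)


@pytest.fixture(scope="session")
def exact_calibration():
    return CantileverCalibration(k_p_mean=20e-3, k_p_sd=0.0, n_obs=5)


@pytest.fixture(scope="session")
def exact_geometry_measurement():
    return GeometryMeasurement(R0_mean=30e-6, R0_sd=0.0, L0_mean=60e-6, L0_sd=0.0)


@pytest.fixture(scope="session")
def simulated_experiment(cell, base_config):
    """One reference simulation (R0 = 30 um, L0 = 60 um), reused read-only."""
    net, trace, truth = simulate_experiment(30e-6, 60e-6, cell, base_config)
    return trace, truth


@pytest.fixture(scope="session")
def rendered_stack(simulated_experiment, reference_geometry, base_config):
    trace, _ = simulated_experiment
    return render_frames(trace, reference_geometry, base_config)


@pytest.fixture()
def noise_free_config(base_config):
    return dataclasses.replace(base_config, noise_sd=0.0, pixel_noise_sd=0.0)


def make_linear_trace(x_px, cfg, frame_rate=30.0):
    """Trace whose deflection follows a prescribed pixel trajectory.

    The motor position is set equal to the deflection so the rendered
    aggregate keeps a constant length (only the sensor tip moves).
    """
    from mfstretch.aggregate_sim import SimulatedTrace

    x = np.asarray(x_px, dtype=float) * cfg.pixel_size
    n = x.size
    return SimulatedTrace(
        t=np.arange(n) / frame_rate,
        x_s=x.copy(),
        x=x.copy(),
        F=np.zeros(n),
        ruptured_at=None,
        x_true=x.copy(),
    )
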