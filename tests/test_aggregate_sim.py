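"""Quasi-static stretch simulator, renderer and group-table generator."""

import dataclasses
import math

import numpy as np
import pandas as pd
import pytest

from mfstretch.exceptions import InvalidConfigurationError, InvalidParameterError
from mfstretch.aggregate_sim import (
    CylinderGeometry,
    ExperimentConfig,
    default_tip_roi,
    generate_group_dataset,
    motor_position,
    render_frames,
    simulate_experiment,
    simulate_stretch,
    FrameStack,
)
from mfstretch.springmodel import CellModel, build_lattice_aggregate, network_stiffness


@pytest.fixture()
def quiet_cfg():
    return ExperimentConfig(seed=0, noise_sd=0.0, t_max=3.0)


class TestMotorKinematics:
    def test_trapezoid_profile(self):
        cfg = ExperimentConfig()
        t_a = cfg.v / cfg.accel  # 20 ms ramp
        assert motor_position(t_a / 2, cfg) == pytest.approx(0.5 * cfg.accel * (t_a / 2) ** 2)
        # after the ramp: v*t minus the constant ramp deficit v^2/(2a)
        assert motor_position(1.0, cfg) == pytest.approx(cfg.v * 1.0 - cfg.v**2 / (2 * cfg.accel))

    def test_ramp_can_be_disabled(self):
        cfg = ExperimentConfig(accel_phase=False)
        t = np.linspace(0, 2, 7)
        assert motor_position(t, cfg) == pytest.approx(cfg.v * t)


class TestSimulateStretch:
    def test_rigid_cantilever_limit(self, cell, quiet_cfg):
        net = build_lattice_aggregate(10e-6, 20e-6, cell)
        k_net = network_stiffness(net).k_eff
        cfg = dataclasses.replace(quiet_cfg, k_p=1e6 * k_net, t_max=0.5)
        trace, _ = simulate_stretch(net, cfg)
        assert np.all(np.abs(trace.x) <= 2e-6 * trace.x_s.max())
        assert trace.x_s == pytest.approx(motor_position(trace.t, cfg))

    def test_rigid_aggregate_limit(self, quiet_cfg):
        stiff_cell = CellModel(k_c=1e6 * 20e-3, yield_strain=1e9, rupture_strain=2e9)
        net = build_lattice_aggregate(10e-6, 20e-6, stiff_cell)
        cfg = dataclasses.replace(quiet_cfg, t_max=0.5)
        trace, _ = simulate_stretch(net, cfg)
        late = trace.t > 0.1
        assert trace.x[late] == pytest.approx(trace.x_s[late], rel=1e-4)

    def test_elastic_phase_closed_form(self, quiet_cfg):
        elastic_cell = CellModel(yield_strain=1e9, rupture_strain=2e9)
        net = build_lattice_aggregate(30e-6, 60e-6, elastic_cell)
        k_net = network_stiffness(net).k_eff
        trace, _ = simulate_stretch(net, quiet_cfg)
        pred = quiet_cfg.k_p * k_net / (quiet_cfg.k_p + k_net) * trace.x_s
        mask = trace.x_s > 0
        assert np.abs(trace.F[mask] - pred[mask]).max() <= 1e-8 * pred[mask].max()
        # force equals both k_p x and the network tension at dL
        assert trace.F[mask] == pytest.approx(quiet_cfg.k_p * trace.x[mask], rel=1e-8)

    def test_kinematic_conservation(self, cell, quiet_cfg):
        net = build_lattice_aggregate(20e-6, 40e-6, cell, threshold_cv=0.2)
        trace, _ = simulate_stretch(net, quiet_cfg)
        dL = trace.x_s - trace.x
        assert trace.x + dL == pytest.approx(trace.x_s, abs=1e-18)
        assert np.all(np.diff(trace.x_s) >= 0)
        assert np.all(trace.x >= -1e-18) and np.all(trace.x <= trace.x_s + 1e-18)

    def test_ductile_curve_shape(self, cell, quiet_cfg):
        """Linear regime, then decreasing slope, a maximum, then rupture."""
        _, trace, truth = simulate_experiment(
            30e-6, 60e-6, cell, dataclasses.replace(quiet_cfg, t_max=6.0)
        )
        assert trace.ruptured_at is not None
        area = math.pi * truth.R0**2
        sigma = trace.F / area
        eps = (trace.x_s - trace.x) / truth.L0
        peak = sigma.argmax()
        assert 0 < peak < trace.t.size - 1  # maximum strictly inside the trace
        early = np.polyfit(eps[2:10], sigma[2:10], 1)[0]
        late = np.polyfit(eps[peak - 8 : peak], sigma[peak - 8 : peak], 1)[0]
        assert late < 0.8 * early  # plastic regime has a smaller slope
        assert sigma[-1] == 0.0  # fully ruptured

    def test_single_spring_network_is_legal(self, quiet_cfg):
        cell = CellModel(yield_strain=1e9, rupture_strain=2e9)
        net = build_lattice_aggregate(cell.r_c, 2 * cell.r_c, cell)
        trace, truth = simulate_stretch(net, dataclasses.replace(quiet_cfg, t_max=0.2))
        assert truth.k_eff0 == pytest.approx(cell.k_c, rel=1e-10)

    def test_ground_truth_modulus(self, cell, quiet_cfg):
        net = build_lattice_aggregate(30e-6, 60e-6, cell)
        _, truth = simulate_stretch(net, quiet_cfg)
        k0 = network_stiffness(build_lattice_aggregate(30e-6, 60e-6, cell)).k_eff
        assert truth.E_true == pytest.approx(k0 * 60e-6 / (math.pi * (30e-6) ** 2))


class TestRenderFrames:
    def test_stationary_tip_for_zero_deflection(self, reference_geometry, base_config):
        from conftest import make_linear_trace

        cfg = dataclasses.replace(base_config, pixel_noise_sd=0.0)
        trace = make_linear_trace(np.zeros(4), cfg)
        stack = render_frames(trace, reference_geometry, cfg)
        assert np.array_equal(stack.frames[0], stack.frames[1])

    def test_first_frame_silhouette_width(self, rendered_stack, reference_geometry, base_config):
        frame0 = rendered_stack.frames[0].astype(float)
        dark = frame0 < (frame0.max() + frame0.min()) / 2
        H = frame0.shape[0]
        # column through the aggregate centre, away from both pipettes
        col = int(frame0.shape[1] - 64 - reference_geometry.L0 / base_config.pixel_size / 2)
        height = dark[:, col].sum()
        expected = 2 * reference_geometry.R0 / base_config.pixel_size
        assert abs(height - expected) <= 2.0  # within a pixel per edge

    def test_field_of_view_too_small(self, reference_geometry, base_config):
        from conftest import make_linear_trace

        cfg = dataclasses.replace(base_config, image_shape=(256, 160))
        trace = make_linear_trace(np.zeros(3), cfg)
        with pytest.raises(InvalidConfigurationError):
            render_frames(trace, reference_geometry, cfg)

    def test_tiff_round_trip(self, rendered_stack, tmp_path):
        path = tmp_path / "frames.tif"
        rendered_stack.save(path)
        back = FrameStack.load(path)
        assert np.array_equal(back.frames, rendered_stack.frames)
        assert back.pixel_size == rendered_stack.pixel_size
        assert back.timestamps == pytest.approx(rendered_stack.timestamps)


class TestGroupDataset:
    def test_deterministic_under_seed(self):
        a = generate_group_dataset(seed=11)
        b = generate_group_dataset(seed=11)
        assert a.equals(b)
        c = generate_group_dataset(seed=12)
        assert not a.equals(c)

    def test_reference_pooled_moments(self):
        df = generate_group_dataset(n_per_group=40, seed=3,
                                    n_aggregates_per_mouse=20)
        ref = df.loc[df.group == "PMA+I", "E_Pa"]
        assert ref.mean() == pytest.approx(248.0, rel=0.10)
        assert ref.std() == pytest.approx(234.0, rel=0.20)

    def test_condition_ratio_scales_within_mouse(self):
        df = generate_group_dataset(seed=0)
        means = df.groupby(["group", "mouse_id"])["E_Pa"].mean().unstack()
        # the mouse baseline cancels exactly in expectation; check the scale
        ratio = (means.loc["PMA+I+W7"] / means.loc["PMA+I"]).mean()
        assert ratio == pytest.approx(2.8, rel=0.25)

    def test_unknown_group_name_rejected(self):
        with pytest.raises(InvalidParameterError):
            generate_group_dataset(["PMA+I", "bogus"], seed=0)

    def test_needs_two_mice(self):
        with pytest.raises(InvalidParameterError):
            generate_group_dataset(n_per_group=1, seed=0)

    def test_covariates_present_and_in_range(self):
        df = generate_group_dataset(seed=5)
        assert set(df.columns) >= {
            "group", "mouse_id", "E_Pa", "V_um3", "V_over_Vtot",
            "hours_post_activation",
        }
        assert df.V_um3.between(1e4, 7e5).all()
        assert df.V_over_Vtot.between(0, 1).all()
        assert (df.E_Pa > 0).all()
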