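"""Engineering stress-strain pipeline: curve, errors, fits, QC, double stretch."""

import dataclasses
import math

import numpy as np
import pytest

from mfstretch.aggregate_sim import (
    ExperimentConfig,
    SimulatedTrace,
    simulate_double_stretch,
    simulate_experiment,
)
from mfstretch.calibration import CantileverCalibration
from mfstretch.exceptions import InsufficientDataError
from mfstretch.mechanics import (
    StretchRecording,
    StressStrainCurve,
    analyze_recording,
    double_stretch_analysis,
    fit_young_modulus,
    propagate_errors,
    qc_validate,
    stress_strain,
    ultimate_tensile_strength,
)
from mfstretch.tracking import GeometryMeasurement


def make_trace(t, x, x_s=None, ruptured_at=None):
    t = np.asarray(t, dtype=float)
    x = np.asarray(x, dtype=float)
    return SimulatedTrace(
        t=t, x_s=np.asarray(x_s, dtype=float) if x_s is not None else None,
        x=x, F=np.zeros_like(x), ruptured_at=ruptured_at, x_true=x,
    )


def make_curve(eps, sigma):
    eps = np.asarray(eps, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    return StressStrainCurve(
        eps=eps, sigma=sigma, eps_err=np.zeros_like(eps),
        sigma_err=np.zeros_like(sigma), frame_index=np.arange(eps.size),
    )


class TestStressStrain:
    def test_hand_values(self, exact_geometry_measurement):
        # k_p = 20 nN/um, x = 5 um, R0 = 30 um -> 35.4 Pa; v t = 20 um -> eps 0.25
        cal = CantileverCalibration(k_p_mean=20e-3, k_p_sd=0.0, n_obs=3)
        trace = make_trace(t=[0.0, 1.0], x=[0.0, 5e-6], x_s=[0.0, 20e-6])
        rec = StretchRecording(calibration=cal, geometry=exact_geometry_measurement,
                               trace=trace)
        curve = stress_strain(rec)
        assert curve.sigma[1] == pytest.approx(35.4, rel=1e-3)
        assert curve.eps[1] == pytest.approx(0.25, rel=1e-12)

    def test_free_motor_limit(self, exact_calibration, exact_geometry_measurement):
        t = np.linspace(0, 2, 20)
        trace = make_trace(t=t, x=np.zeros_like(t))  # x_s defaults to v t
        rec = StretchRecording(calibration=exact_calibration,
                               geometry=exact_geometry_measurement, trace=trace)
        curve = stress_strain(rec)
        assert curve.sigma == pytest.approx(np.zeros_like(t))
        assert curve.eps == pytest.approx(rec.v * t / 60e-6)

    def test_matches_simulator_internals(self, cell, exact_calibration,
                                          exact_geometry_measurement):
        cfg = ExperimentConfig(seed=4, noise_sd=0.0)
        _, trace, truth = simulate_experiment(30e-6, 60e-6, cell, cfg)
        rec = StretchRecording(calibration=exact_calibration,
                               geometry=exact_geometry_measurement, trace=trace)
        curve = stress_strain(rec)
        area = math.pi * truth.R0**2
        assert curve.sigma == pytest.approx(trace.F / area, rel=1e-10)
        assert curve.eps == pytest.approx((trace.x_s - trace.x) / truth.L0)

    def test_kinematic_identity(self, cell, exact_calibration,
                                exact_geometry_measurement):
        cfg = ExperimentConfig(seed=4, noise_sd=0.0)
        _, trace, _ = simulate_experiment(30e-6, 60e-6, cell, cfg)
        rec = StretchRecording(calibration=exact_calibration,
                               geometry=exact_geometry_measurement, trace=trace)
        curve = stress_strain(rec)
        assert curve.eps * 60e-6 + trace.x == pytest.approx(trace.x_s, abs=1e-15)

    def test_scale_invariance_in_kp(self, exact_geometry_measurement):
        t = np.linspace(0, 2, 30)
        x = 1e-6 * t
        for c in (1.0, 3.7):
            cal = CantileverCalibration(k_p_mean=c * 20e-3, k_p_sd=0.0, n_obs=3)
            rec = StretchRecording(calibration=cal,
                                   geometry=exact_geometry_measurement,
                                   trace=make_trace(t, x))
            curve = stress_strain(rec)
            E, _, _ = fit_young_modulus(curve)
            if c == 1.0:
                base_sigma, base_E = curve.sigma.copy(), E
        assert curve.sigma == pytest.approx(3.7 * base_sigma, rel=1e-12)
        assert E == pytest.approx(3.7 * base_E, rel=1e-12)


class TestErrorPropagation:
    def test_zero_sds_give_zero_errors(self, exact_calibration,
                                       exact_geometry_measurement):
        curve = make_curve([0.1, 0.2], [10.0, 20.0])
        propagate_errors(curve, exact_calibration, exact_geometry_measurement)
        assert np.all(curve.sigma_err == 0.0) and np.all(curve.eps_err == 0.0)

    def test_hand_value(self):
        # 3% on k_p and 4% on R0 -> sigma_err/sigma = sqrt(0.03^2 + 0.08^2) = 8.54%
        cal = CantileverCalibration(k_p_mean=20e-3, k_p_sd=0.03 * 20e-3, n_obs=5)
        geom = GeometryMeasurement(R0_mean=30e-6, R0_sd=0.04 * 30e-6,
                                   L0_mean=60e-6, L0_sd=0.0)
        curve = make_curve([0.2], [50.0])
        propagate_errors(curve, cal, geom)
        assert curve.sigma_err[0] / 50.0 == pytest.approx(0.08544, rel=1e-3)
        assert curve.eps_err[0] == 0.0

    @pytest.mark.parametrize("rel", [0.03, 0.05, 0.10])
    def test_against_monte_carlo(self, rel):
        """First-order formulas vs 1e4-draw MC with log-normal perturbations."""
        kp, R0, L0 = 20e-3, 30e-6, 60e-6
        x, xs = 5e-6, 20e-6
        cal = CantileverCalibration(k_p_mean=kp, k_p_sd=rel * kp, n_obs=5)
        geom = GeometryMeasurement(R0_mean=R0, R0_sd=rel * R0,
                                   L0_mean=L0, L0_sd=rel * L0)
        curve = make_curve([(xs - x) / L0], [kp * x / (math.pi * R0**2)])
        propagate_errors(curve, cal, geom)

        rng = np.random.default_rng(0)
        s = math.sqrt(math.log(1 + rel**2))
        n = 10_000
        kps = kp * np.exp(rng.normal(-s * s / 2, s, n))
        r0s = R0 * np.exp(rng.normal(-s * s / 2, s, n))
        l0s = L0 * np.exp(rng.normal(-s * s / 2, s, n))
        sigma_mc = (kps * x / (math.pi * r0s**2)).std()
        eps_mc = ((xs - x) / l0s).std()
        assert curve.sigma_err[0] == pytest.approx(sigma_mc, rel=0.05)
        assert curve.eps_err[0] == pytest.approx(eps_mc, rel=0.05)


class TestModulusFit:
    def test_exact_line(self):
        eps = np.linspace(0, 0.4, 40)
        curve = make_curve(eps, 250.0 * eps)
        E, E_err, window = fit_young_modulus(curve)
        assert E == pytest.approx(250.0, rel=1e-9)
        assert E_err == pytest.approx(0.0, abs=1e-6)
        assert window == (0, 29)  # ties resolved towards the largest window

    def test_window_avoids_plastic_rolloff(self):
        eps = np.linspace(0, 0.4, 40)
        sigma = np.where(eps <= eps[14], 250.0 * eps,
                         250.0 * eps[14] + 25.0 * (eps - eps[14]))
        curve = make_curve(eps, sigma)
        E, _, (first, last) = fit_young_modulus(curve)
        assert last <= 17  # selected window ends near the kink at point 15
        assert E == pytest.approx(250.0, rel=0.10)

    def test_insufficient_points(self):
        curve = make_curve([0.0, 0.1], [0.0, 10.0])
        with pytest.raises(InsufficientDataError):
            fit_young_modulus(curve)

    def test_simulated_curve_recovers_network_modulus(
        self, cell, exact_calibration, exact_geometry_measurement
    ):
        cfg = ExperimentConfig(seed=9, noise_sd=0.0)
        _, trace, truth = simulate_experiment(30e-6, 60e-6, cell, cfg)
        rec = StretchRecording(calibration=exact_calibration,
                               geometry=exact_geometry_measurement, trace=trace)
        E, _, _ = fit_young_modulus(stress_strain(rec))
        assert E == pytest.approx(truth.E_true, rel=0.05)


class TestUTSAndQC:
    def test_uts_is_max_of_curve(self):
        curve = make_curve(np.linspace(0, 1, 30), np.linspace(0, 390.0, 30))
        assert ultimate_tensile_strength(curve) == pytest.approx(390.0)

    def test_slip_discards_uts_but_not_modulus(
        self, cell, exact_calibration, exact_geometry_measurement
    ):
        cfg = ExperimentConfig(seed=2, noise_sd=0.0)
        _, trace, _ = simulate_experiment(30e-6, 60e-6, cell, cfg)
        rec = StretchRecording(calibration=exact_calibration,
                               geometry=exact_geometry_measurement, trace=trace)
        props = analyze_recording(rec, annotations=("slip",))
        assert props.sigma_uts is None
        assert props.valid and props.E is not None

    def test_uts_matches_simulator_ground_truth(
        self, cell, exact_calibration, exact_geometry_measurement
    ):
        cfg = ExperimentConfig(seed=2, noise_sd=0.0)
        _, trace, truth = simulate_experiment(30e-6, 60e-6, cell, cfg)
        rec = StretchRecording(calibration=exact_calibration,
                               geometry=exact_geometry_measurement, trace=trace)
        uts = ultimate_tensile_strength(stress_strain(rec))
        assert uts == pytest.approx(truth.sigma_uts_true, rel=1e-9)

    def test_smooth_curve_has_no_flags(
        self, cell, exact_calibration, exact_geometry_measurement
    ):
        cfg = ExperimentConfig(seed=2, noise_sd=0.0)
        _, trace, _ = simulate_experiment(30e-6, 60e-6, cell, cfg)
        rec = StretchRecording(calibration=exact_calibration,
                               geometry=exact_geometry_measurement, trace=trace)
        assert qc_validate(rec, stress_strain(rec)) == set()

    def test_injected_jump_is_flagged(self, exact_calibration,
                                      exact_geometry_measurement):
        t = np.linspace(0, 2, 40)
        x = 1e-6 * t
        x[20] += 20 * 1e-6 * (t[1] - t[0]) * 20  # 20x the median deflection step
        trace = make_trace(t, x)
        rec = StretchRecording(calibration=exact_calibration,
                               geometry=exact_geometry_measurement, trace=trace)
        curve = stress_strain(rec)
        assert "jump" in qc_validate(rec, curve)

    def test_rupture_at_onset_flagged_no_stretch(
        self, exact_calibration, exact_geometry_measurement
    ):
        t = np.linspace(0, 1, 30)
        x = np.zeros_like(t)
        trace = make_trace(t, x, x_s=0.3e-6 * t, ruptured_at=3)
        rec = StretchRecording(calibration=exact_calibration,
                               geometry=exact_geometry_measurement, trace=trace)
        curve = stress_strain(rec)
        flags = qc_validate(rec, curve)
        assert "no_stretch" in flags
        props = analyze_recording(rec)
        assert not props.valid

    def test_invalid_experiment_still_produces_row(
        self, exact_calibration, exact_geometry_measurement
    ):
        t = np.linspace(0, 1, 30)
        trace = make_trace(t, np.zeros_like(t), x_s=0.3e-6 * t, ruptured_at=2)
        rec = StretchRecording(calibration=exact_calibration,
                               geometry=exact_geometry_measurement, trace=trace,
                               label="bad-experiment")
        props = analyze_recording(rec)
        assert props.label == "bad-experiment"
        assert props.E is None and not props.valid


class TestDoubleStretch:
    def test_identical_recordings_give_unit_ratio(
        self, cell, exact_calibration, exact_geometry_measurement
    ):
        cfg = ExperimentConfig(seed=6, noise_sd=0.0)
        _, trace, _ = simulate_experiment(30e-6, 60e-6, cell, cfg)
        rec = StretchRecording(calibration=exact_calibration,
                               geometry=exact_geometry_measurement, trace=trace)
        res = double_stretch_analysis(rec, rec)
        assert res.ratio == pytest.approx(1.0, rel=1e-12)
        assert res.eps1_max == pytest.approx(
            float(stress_strain(rec).eps.max())
        )

    def test_softening_factor_recovered(
        self, cell, exact_calibration, exact_geometry_measurement
    ):
        cfg = ExperimentConfig(seed=6, noise_sd=0.0)
        (t1, _), (t2, _) = simulate_double_stretch(
            30e-6, 60e-6, cell, cfg, eps1_max=0.3, softening=0.7
        )
        rec1 = StretchRecording(calibration=exact_calibration,
                                geometry=exact_geometry_measurement, trace=t1)
        rec2 = StretchRecording(calibration=exact_calibration,
                                geometry=exact_geometry_measurement, trace=t2)
        res = double_stretch_analysis(rec1, rec2)
        assert res.ratio == pytest.approx(0.7, rel=0.10)
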