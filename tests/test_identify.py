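"""PD controller, trial simulation, error metrics, and the strength
calibration loop."""

import math

import numpy as np
import pytest

from conftest import single_cycle_trace
from isospine.identify import (
    CalibrationConfig,
    ControllerParams,
    PDController,
    StrengthIdentifier,
    calibrate_strength,
    metrics,
    personalize_fiber_length,
    simulate_isokinetic_moment,
    simulate_trial,
)
from isospine.plant import IsokineticProtocol, default_plant
from isospine.synergy import SynergyCoupling
from isospine.synthetic import make_measured_trace, make_subject


class TestPDController:
    def test_zero_error_leaves_command_unchanged(self, plant):
        ctrl = PDController(ControllerParams(), plant)
        ref = lambda t: 0.1
        for k in range(5):
            acts = ctrl.update(k * 0.01, ref, 0.1, 10.0)
        assert all(c == 0.0 for c in ctrl.command.values())
        assert all(a == 0.02 for a in acts.values())

    def test_constant_error_increments_by_kp_e(self):
        # single-fascicle groups -> PCSA share 1
        plant = default_plant()
        plant.muscles = [m for m in plant.muscles if m.name in ("ES", "RA")]
        ctrl = PDController(ControllerParams(), plant)
        ref = lambda t: 0.0
        e = 0.15
        ctrl.update(0.0, ref, e, 10.0)
        c1 = ctrl.command["ES"]
        ctrl.update(0.01, ref, e, 10.0)
        c2 = ctrl.command["ES"]
        assert c1 == pytest.approx(0.05 * e)
        assert c2 - c1 == pytest.approx(0.05 * e)

    def test_saturation_and_floor(self, plant):
        ctrl = PDController(ControllerParams(), plant)
        ref = lambda t: 0.0
        for k in range(600):
            acts = ctrl.update(k * 0.01, ref, 1.0, 100.0)  # huge extension error
        assert acts["ES"] == 1.0 and acts["MF"] == 1.0
        assert acts["RA"] == 0.02 and acts["PM"] == 0.02
        ctrl.reset()
        for k in range(600):
            acts = ctrl.update(k * 0.01, ref, -1.0, 100.0)
        assert acts["RA"] == 1.0 and acts["ES"] == 0.02

    def test_synergy_coupling_never_decreases_antagonist(self, plant):
        coup = SynergyCoupling(0.3, 0.6, 0.2, 0.8)
        base = PDController(ControllerParams(), plant)
        syn = PDController(ControllerParams(), plant, coupling=coup, with_synergy=True)
        ref = lambda t: 0.0
        for k in range(200):
            a0 = base.update(k * 0.01, ref, 0.5, 100.0, "Ext")
            a1 = syn.update(k * 0.01, ref, 0.5, 100.0, "Ext")
        for n in ("RA", "PM"):
            assert a1[n] >= a0[n]
        assert a1["RA"] == pytest.approx(0.5 * a0["ES"], abs=1e-9)


class TestMetrics:
    def test_identical_traces(self):
        tr = single_cycle_trace(100.0, -60.0, cycles=3)
        rep = metrics(tr, tr)
        assert rep.percent_error_ext == 0.0
        assert rep.percent_error_flex == 0.0
        assert rep.pearson_r == pytest.approx(1.0)
        assert rep.rmse_angle_deg == 0.0

    @pytest.mark.parametrize(
        "meas, sim, expected",
        [
            (194.30, 223.03, 14.79),
            (216.20, 217.13, 0.43),
            (101.18, 97.94, 3.20),
            (194.30, 185.83, 4.36),
        ],
    )
    def test_extension_error_arithmetic(self, meas, sim, expected):
        with pytest.warns(UserWarning):
            rep = metrics(single_cycle_trace(meas, -50.0), single_cycle_trace(sim, -50.0))
        assert round(rep.percent_error_ext, 2) == expected

    def test_flexion_error_arithmetic(self):
        with pytest.warns(UserWarning):
            rep = metrics(
                single_cycle_trace(100.0, -173.68), single_cycle_trace(100.0, -173.67)
            )
        assert round(rep.percent_error_flex, 2) == 0.01


class TestSimulateTrial:
    def test_passive_symmetric_plant_without_gravity_is_quiet(self, short_protocol):
        # no gravity, no bushing stiffness, fibers kept below optimal
        # length (no PE engagement): nothing drives a muscle moment, so
        # the recorded passive moment is quiet away from the lever's
        # velocity steps (which transiently excite the trunk inertia)
        plant = default_plant(gravity_on=False)
        plant.geometry.ivd_stiffness = 1e-9
        plant.geometry.ivd_damping = 0.0
        for m in plant.muscles:
            plant.geometry.mt_length_ref[m.name] = m.tendon_slack + 0.6 * m.l0
        res = simulate_trial(plant, short_protocol, None, passive=True)
        t = res.trace.time
        # the underdamped trunk-lever coupling rings for ~0.5 s after each
        # lever velocity step; judge quietness on the steady windows
        steady = np.minimum(t % 2.0, 2.0 - (t % 2.0)) >= 0.6
        assert np.max(np.abs(res.trace.moment[steady])) < 0.5

    def test_zero_activation_active_run_equals_passive_run(self, short_protocol, plant):
        init = plant.initialize_posture(math.radians(30.0))
        a = simulate_trial(plant, short_protocol, None, passive=True, init_state=init)
        b = simulate_trial(plant, short_protocol, None, passive=False, init_state=init)
        assert np.allclose(a.trace.moment, b.trace.moment)

    def test_closed_loop_tracking_rmse_below_two_degrees(self, plant):
        protocol = IsokineticProtocol(cycles=3)
        ctrl = PDController(ControllerParams(), plant)
        res = simulate_trial(plant, protocol, ctrl)
        lever = res.lever_angle_deg
        rmse = float(np.sqrt(np.mean((res.trace.angle_deg - lever) ** 2)))
        assert rmse < 2.0


class TestCalibration:
    def test_self_consistent_measurement_needs_no_update(self, plant):
        # "measured" trace = the plant's own simulation -> betas ~ 1
        protocol = IsokineticProtocol(cycles=3)
        ctrl = PDController(ControllerParams(), plant)
        misom, _, _ = simulate_isokinetic_moment(plant, protocol, ctrl)
        measured = type(misom)(misom.time, protocol.angle_deg(misom.time), misom.moment)
        res = calibrate_strength(measured, plant)
        assert res.converged and res.n_iter == 1
        assert res.beta_ext[0] == pytest.approx(1.0, abs=0.05)
        assert res.beta_flex[0] == pytest.approx(1.0, abs=0.05)
        assert res.f0_scale_ext[-1] == 1.0  # no update applied

    def test_recovers_planted_extensor_scale(self):
        sub = make_subject(11, moment_noise_sd=0.0)
        sub.f0_scale["extensor"] = 1.5
        sub.f0_scale["flexor"] = 1.0
        sub.planted_W[:, :] = np.where(
            sub.planted_W > 0.5, sub.planted_W, 0.01
        )  # suppress co-contraction to isolate the strength mechanism
        trace, _ = make_measured_trace(sub)
        res = calibrate_strength(trace, default_plant())
        assert res.converged
        assert res.beta_ext[-1] == pytest.approx(1.0, abs=0.2)
        assert res.f0_scale_ext[-1] == pytest.approx(1.5, rel=0.20)

    def test_monotone_beta_correction(self):
        sub = make_subject(12, moment_noise_sd=0.0)
        trace, _ = make_measured_trace(sub)
        res = calibrate_strength(trace, default_plant())
        gaps = [abs(b - 1.0) for b in res.beta_ext]
        assert all(b <= a + 1e-6 for a, b in zip(gaps, gaps[1:]))

    def test_synergy_raises_identified_agonist_strength(self):
        sub = make_subject(13, moment_noise_sd=0.0)
        trace, _ = make_measured_trace(sub)
        coup = SynergyCoupling(0.25, 0.8, 0.3, 0.85)
        base = calibrate_strength(trace, default_plant())
        syn = calibrate_strength(
            trace, default_plant(),
            config=CalibrationConfig(with_synergy=True), coupling=coup,
        )
        assert syn.f0_scale_ext[-1] >= base.f0_scale_ext[-1]
        assert syn.f0_scale_flex[-1] >= base.f0_scale_flex[-1]

    def test_iap_weakly_lowers_extensor_strength(self):
        sub = make_subject(14, moment_noise_sd=0.0)
        trace, _ = make_measured_trace(sub)
        base = calibrate_strength(trace, default_plant())
        iap = calibrate_strength(
            trace, default_plant(), config=CalibrationConfig(with_iap=True)
        )
        assert iap.f0_scale_ext[-1] <= base.f0_scale_ext[-1] + 1e-9


class TestPersonalizeFiberLength:
    def test_peak_lengths_average_into_l0(self, plant):
        protocol = IsokineticProtocol(cycles=3)
        ctrl = PDController(ControllerParams(), plant)
        misom, active, _ = simulate_isokinetic_moment(plant, protocol, ctrl)
        new_plant = personalize_fiber_length(active, misom, plant)
        es_new = new_plant.muscle("ES").l0
        # extensor peaks occur past neutral toward extension, where the
        # ES fiber is shorter than its reference optimum
        assert 0.8 * plant.muscle("ES").l0 < es_new < 1.1 * plant.muscle("ES").l0
        assert new_plant.muscle("RA").l0 != plant.muscle("RA").l0

    def test_requires_two_cycles(self, plant):
        protocol = IsokineticProtocol(cycles=1)
        ctrl = PDController(ControllerParams(), plant)
        misom, active, _ = simulate_isokinetic_moment(plant, protocol, ctrl)
        with pytest.raises(ValueError, match="insufficient"):
            personalize_fiber_length(active, misom, plant)

    def test_optimum_target_divides_by_ninety_five_percent(self, plant):
        protocol = IsokineticProtocol(cycles=2)
        ctrl = PDController(ControllerParams(), plant)
        misom, active, _ = simulate_isokinetic_moment(plant, protocol, ctrl)
        at_l0 = personalize_fiber_length(active, misom, plant, target="l0")
        at_opt = personalize_fiber_length(active, misom, plant, target="optimum")
        assert at_opt.muscle("ES").l0 == pytest.approx(at_l0.muscle("ES").l0 / 0.95)
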