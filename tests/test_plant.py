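"""Trunk plant: kinematic maps, gravity/IAP moments, forward dynamics,
dynamic relaxation, and energy sanity."""

import copy
import math

import numpy as np
import pytest

from isospine.plant import (
    IapParams,
    IsokineticProtocol,
    PlantState,
    default_plant,
)


class TestMuscleTendonKinematics:
    def test_reference_length_at_neutral(self, plant):
        for m in plant.muscles:
            assert plant.mt_length(0.0, m.name) == pytest.approx(
                plant.geometry.mt_length_ref[m.name]
            )

    def test_extensor_lengthens_under_flexion(self, plant):
        # extensor arm +0.055 m, +0.1 rad flexion -> +0.0055 m
        d = plant.mt_length(0.1, "ES") - plant.mt_length(0.0, "ES")
        assert d == pytest.approx(0.055 * 0.1)

    def test_flexor_shortens_under_flexion(self, plant):
        assert plant.mt_length(0.1, "RA") < plant.mt_length(0.0, "RA")

    def test_rate_is_arm_times_omega(self, plant):
        # d(mt_length)/d(theta) equals the signed arm exactly
        for m in plant.muscles:
            arm = plant.geometry.moment_arm[m.name]
            num = (plant.mt_length(0.2001, m.name) - plant.mt_length(0.2, m.name)) / 1e-4
            assert num == pytest.approx(arm, rel=1e-6)
            assert plant.mt_velocity(0.5, m.name) == pytest.approx(arm * 0.5)


class TestGravityMoment:
    def test_zero_at_upright(self, plant):
        assert plant.gravity_moment(0.0) == 0.0

    def test_full_horizontal_arm(self, plant):
        g = plant.geometry
        expected = -g.trunk_mass * 9.81 * g.com_distance
        assert plant.gravity_moment(math.pi / 2) == pytest.approx(expected)

    def test_odd_symmetry(self, plant):
        for th in (0.1, 0.3, 0.5):
            assert plant.gravity_moment(-th) == pytest.approx(-plant.gravity_moment(th))


class TestIapMoment:
    schedule = [(0.0, 2.0, "Flx"), (2.0, 4.0, "Ext")]

    def test_zero_peak_pressure(self):
        plant = default_plant(iap=IapParams(peak_pressure=0.0))
        assert plant.iap_moment(1.0, self.schedule) == 0.0

    def test_linear_ramp_midpoint(self, plant):
        expected = 0.5 * plant.iap.plateau_moment
        assert plant.iap_moment(0.25, self.schedule) == pytest.approx(expected)
        assert plant.iap_moment(2.25, self.schedule) == pytest.approx(expected)

    def test_plateau_value(self, plant):
        assert plant.iap_moment(1.0, self.schedule) == pytest.approx(
            plant.iap.peak_pressure * plant.iap.diaphragm_area * plant.iap.pressure_arm
        )

    def test_release_before_phase_end(self, plant):
        assert plant.iap_moment(1.75, self.schedule) == pytest.approx(
            0.5 * plant.iap.plateau_moment
        )
        assert plant.iap_moment(4.5, self.schedule) == 0.0  # outside schedule


class TestStepDynamics:
    def test_equilibrium_holds_without_drive(self):
        plant = default_plant(gravity_on=False)
        acts = {m.name: 0.0 for m in plant.muscles}
        st = PlantState(0.0, 0.0, 0.0, 0.0)
        out = plant.step_dynamics(st, acts, lambda t: 0.0, lambda t: 0.0, n_steps=200)
        assert abs(out.theta) < 1e-9 and abs(out.omega) < 1e-9

    def test_static_torque_balance(self, plant):
        # constant extensor drive, lever fixed: coupling balances muscle+gravity+ivd
        st0 = plant.initialize_posture(0.0)
        acts = {m.name: 0.0 for m in plant.muscles}
        acts["ES"] = 0.5
        st = PlantState(st0.theta, 0.0, 0.0, 0.0)
        st = plant.step_dynamics(
            st, acts, lambda t: 0.0, lambda t: 0.0, n_steps=3000, extra_damping=200.0
        )
        es = plant.muscle_state(st.theta, 0.0, 0.5, "ES")
        passive = sum(
            plant.muscle_state(st.theta, 0.0, 0.0, n).f_tend * plant.geometry.moment_arm[n]
            for n in ("MF", "RA", "PM")
        )
        expected = -(
            es.f_tend * plant.geometry.moment_arm["ES"]
            + passive
            + plant.gravity_moment(st.theta)
            + plant.geometry.ivd_stiffness * st.theta
        )
        assert st.coupling_moment == pytest.approx(expected, rel=0.01)

    def test_stiff_spring_insensitivity(self, plant):
        def steady(p):
            st0 = p.initialize_posture(0.0)
            acts = {m.name: 0.0 for m in p.muscles}
            acts["ES"] = 0.5
            st = PlantState(st0.theta, 0.0, 0.0, 0.0)
            return p.step_dynamics(
                st, acts, lambda t: 0.0, lambda t: 0.0, n_steps=3000, extra_damping=200.0
            ).coupling_moment

        stiff = copy.deepcopy(plant)
        stiff.geometry.coupling_stiffness *= 2.0
        c1, c2 = steady(plant), steady(stiff)
        assert abs(c2 - c1) / abs(c1) < 0.01

    def test_internal_step_capped(self, plant):
        st = PlantState(0.0, 0.0, 0.0, 0.0)
        with pytest.raises(ValueError, match="1 ms"):
            plant.step_dynamics(st, {}, lambda t: 0.0, lambda t: 0.0, dt=5e-3)

    def test_energy_dissipates_passively(self):
        # zero activation, fixed lever: total mechanical energy of the
        # trunk (kinetic + coupling/ivd springs + gravity potential)
        # cannot grow; fibers stay below optimal length so the passive
        # elements store nothing
        plant = default_plant(gravity_on=False)
        acts = {m.name: 0.0 for m in plant.muscles}
        g = plant.geometry

        def energy(st):
            return (
                0.5 * g.trunk_inertia * st.omega**2
                + 0.5 * g.coupling_stiffness * st.theta**2
                + 0.5 * g.ivd_stiffness * st.theta**2
            )

        st = PlantState(0.0, 0.4, 0.0, 0.0)  # initial kick, fibers near l0
        energies = []
        for _ in range(30):
            st = plant.step_dynamics(st, acts, lambda t: 0.0, lambda t: 0.0, n_steps=20)
            energies.append(energy(st) + _passive_elastic(plant, st.theta))
        assert all(b <= a + 1e-9 for a, b in zip(energies, energies[1:]))


def _passive_elastic(plant, theta):
    """Closed-form stored energy of the cubic passive fiber elements."""
    total = 0.0
    for m in plant.muscles:
        l = plant.mt_length(theta, m.name) - m.tendon_slack
        r = l / m.l0
        if r > 1.0:
            total += 2.0 * m.f0 * m.l0 * min(r - 1.0, 0.63) ** 4
            if r > 1.63:
                total += 2.0 * m.f0 * (l - 1.63 * m.l0)
    return total


class TestInitializePosture:
    def test_settles_at_lever_without_gravity(self):
        plant = default_plant(gravity_on=False)
        st = plant.initialize_posture(0.2)
        # passive extensor stretch pulls slightly off the lever angle
        assert st.theta == pytest.approx(0.2, abs=5e-3)
        assert abs(st.omega) < 1e-3

    def test_static_balance_residual_under_gravity(self, plant):
        st = plant.initialize_posture(math.radians(30.0))
        resid = plant.net_moment(
            0.0, st.theta, 0.0, {m.name: 0.0 for m in plant.muscles}, st.lever_angle, 0.0
        )[0]
        assert abs(resid) < 0.01

    def test_settled_state_starts_trial_without_transient(self, plant):
        st = plant.initialize_posture(math.radians(30.0))
        acts = {m.name: 0.0 for m in plant.muscles}
        out = plant.step_dynamics(
            st, acts, lambda t: math.radians(30.0), lambda t: 0.0, n_steps=100
        )
        assert abs(out.coupling_moment - st.coupling_moment) < 1.0


class TestProtocol:
    def test_triangle_trajectory(self, protocol):
        assert protocol.angle_deg(0.0) == 30.0
        assert protocol.angle_deg(1.0) == 0.0
        assert protocol.angle_deg(2.0) == -30.0
        assert protocol.angle_deg(3.0) == 0.0
        assert protocol.angle_deg(4.0) == 30.0
        assert protocol.duration == 20.0

    def test_phases_alternate(self, protocol):
        assert protocol.phase(0.5) == "Ext"
        assert protocol.phase(2.5) == "Flx"
        intervals = protocol.phase_intervals()
        assert len(intervals) == 10
        assert intervals[0][2] == "Ext" and intervals[1][2] == "Flx"

    def test_extension_positive_moment_convention(self, plant):
        # an extensor pulling on the trunk yields a positive recorded
        # (reaction) moment: -coupling_moment > 0
        st0 = plant.initialize_posture(0.0)
        acts = {m.name: 0.0 for m in plant.muscles}
        acts["ES"] = 0.8
        st = PlantState(st0.theta, 0.0, 0.0, 0.0)
        st = plant.step_dynamics(
            st, acts, lambda t: 0.0, lambda t: 0.0, n_steps=2000, extra_damping=200.0
        )
        assert -st.coupling_moment > 0
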