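"""One-DOF sagittal trunk surrogate coupled to an isokinetic dynamometer.

The trunk is a single rigid segment rotating about a lumbar hinge,
actuated by lumped flexor/extensor Hill-type fascicles with constant
moment arms, loaded by gravity, a lumped linear intervertebral-disc (IVD)
rotational bushing, an optional intra-abdominal-pressure (IAP) piston
moment, and coupled to the kinematically prescribed dynamometer lever by
a stiff rotational spring-damper.  The coupling torque plays the role of
the dynamometer constraint moment: its reaction is what the device
records.

Conventions: the public angle is flexion-positive (degrees at file I/O,
radians internally); joint moments are reported extension-positive, so a
positive recorded moment means the trunk pushes the lever toward
extension.  A fascicle's moment arm is signed extension-positive
(extensors positive, flexors negative) and its muscle-tendon length is
``mt_length_ref + arm * theta_flexion``: flexing the trunk lengthens the
extensors.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .hill import MuscleParams, MuscleState, TendonConstants, muscle_tendon_force

__all__ = [
    "PlantGeometry",
    "IapParams",
    "IsokineticProtocol",
    "PlantState",
    "TrunkPlant",
    "default_muscles",
    "default_plant",
]

G = 9.81  # m/s^2


@dataclass
class PlantGeometry:
    """Trunk segment and coupling parameters.

    Anthropometry defaults approximate a 78-kg, 175-cm adult male:
    trunk (with head/arms) mass 36 kg, joint-to-COM distance 0.22 m,
    inertia 2.6 kg m^2 about the joint.  ``moment_arm`` and
    ``mt_length_ref`` are per-fascicle maps keyed by muscle name.
    """

    trunk_mass: float = 36.0
    com_distance: float = 0.22
    trunk_inertia: float = 2.6
    moment_arm: dict[str, float] = field(default_factory=dict)
    mt_length_ref: dict[str, float] = field(default_factory=dict)
    ivd_stiffness: float = 15.0
    ivd_damping: float = 1.5
    coupling_stiffness: float = 5000.0
    coupling_damping: float = 50.0

    def __post_init__(self) -> None:
        if min(self.trunk_mass, self.trunk_inertia, self.ivd_stiffness, self.coupling_stiffness) <= 0:
            raise ValueError("mass, inertia and stiffnesses must be positive")


@dataclass
class IapParams:
    """Intra-abdominal-pressure piston: pressure on the diaphragm times its
    area and lever arm gives an extension-assisting moment."""

    peak_pressure: float = 10_000.0  # Pa
    diaphragm_area: float = 0.01  # m^2
    pressure_arm: float = 0.05  # m
    ramp_time: float = 0.5  # s

    def __post_init__(self) -> None:
        if min(self.peak_pressure, self.diaphragm_area, self.pressure_arm, self.ramp_time) < 0:
            raise ValueError("IAP parameters must be non-negative")

    @property
    def plateau_moment(self) -> float:
        return self.peak_pressure * self.diaphragm_area * self.pressure_arm


@dataclass
class IsokineticProtocol:
    """Concentric isokinetic protocol: constant angular speed between the
    flexion and extension limits, starting at full flexion (extension
    phase first)."""

    speed: float = 30.0  # deg/s
    range_deg: tuple[float, float] = (-30.0, 30.0)  # (extension limit, flexion limit)
    cycles: int = 5

    def __post_init__(self) -> None:
        if self.speed <= 0 or self.cycles < 1:
            raise ValueError("speed must be positive and cycles >= 1")
        if self.range_deg[1] <= self.range_deg[0]:
            raise ValueError("range must satisfy min < max")

    @property
    def half_period(self) -> float:
        return (self.range_deg[1] - self.range_deg[0]) / self.speed

    @property
    def duration(self) -> float:
        return 2.0 * self.half_period * self.cycles

    def angle_deg(self, t):
        """Prescribed lever angle (flexion-positive degrees) at time(s) t."""
        t = np.asarray(t, dtype=float)
        lo, hi = self.range_deg
        tau = np.clip(t, 0.0, self.duration) % (2.0 * self.half_period)
        down = hi - self.speed * tau
        up = lo + self.speed * (tau - self.half_period)
        out = np.where(tau < self.half_period, down, up)
        out = np.where(np.asarray(t) >= self.duration, hi, out)
        return out if out.ndim else float(out)

    def rate_deg(self, t):
        """Prescribed lever angular rate (deg/s, flexion-positive)."""
        t = np.asarray(t, dtype=float)
        tau = t % (2.0 * self.half_period)
        out = np.where(tau < self.half_period, -self.speed, self.speed)
        out = np.where((t < 0) | (t >= self.duration), 0.0, out)
        return out if out.ndim else float(out)

    def phase(self, t):
        """Movement phase: 'Ext' while the lever moves toward extension."""
        r = self.rate_deg(t)
        if np.ndim(r) == 0:
            return "Ext" if r < 0 else "Flx"
        return np.where(r < 0, "Ext", "Flx")

    def phase_intervals(self) -> list[tuple[float, float, str]]:
        """(t_start, t_end, phase) for every half-cycle."""
        out = []
        for k in range(2 * self.cycles):
            t0, t1 = k * self.half_period, (k + 1) * self.half_period
            out.append((t0, t1, "Ext" if k % 2 == 0 else "Flx"))
        return out


@dataclass
class PlantState:
    """Trunk state.  theta/omega are flexion-positive rad and rad/s;
    coupling_moment is the extension-positive coupling torque acting on
    the trunk (the device records its negative)."""

    theta: float
    omega: float
    lever_angle: float
    coupling_moment: float
    t: float = 0.0
    muscle_states: dict[str, MuscleState] = field(default_factory=dict)


def default_muscles() -> list[MuscleParams]:
    """Four lumped sagittal fascicles (pennation folded into the lumped
    line of action, alpha = 0)."""
    return [
        MuscleParams("ES", "extensor", f0=2500.0, l0=0.12, v0=1.2, tendon_slack=0.05, pcsa=46.0),
        MuscleParams("MF", "extensor", f0=1500.0, l0=0.10, v0=1.0, tendon_slack=0.03, pcsa=28.0),
        MuscleParams("RA", "flexor", f0=1000.0, l0=0.28, v0=2.8, tendon_slack=0.10, pcsa=18.0),
        MuscleParams("PM", "flexor", f0=1300.0, l0=0.10, v0=1.0, tendon_slack=0.05, pcsa=24.0),
    ]


_DEFAULT_ARMS = {"ES": 0.055, "MF": 0.045, "RA": -0.08, "PM": -0.04}


def default_plant(
    muscles: list[MuscleParams] | None = None,
    iap: IapParams | None = None,
    gravity_on: bool = True,
) -> "TrunkPlant":
    muscles = muscles if muscles is not None else default_muscles()
    geom = PlantGeometry(
        moment_arm=dict(_DEFAULT_ARMS),
        mt_length_ref={m.name: m.tendon_slack + m.l0 for m in muscles},
    )
    return TrunkPlant(geom, muscles, iap=iap, gravity_on=gravity_on)


class TrunkPlant:
    """Forward-dynamic trunk model; see module docstring for conventions."""

    def __init__(
        self,
        geometry: PlantGeometry,
        muscles: list[MuscleParams],
        tendon: TendonConstants | None = None,
        iap: IapParams | None = None,
        elastic_tendon: bool = False,
        gravity_on: bool = True,
    ) -> None:
        for m in muscles:
            if m.name not in geometry.moment_arm or m.name not in geometry.mt_length_ref:
                raise ValueError(f"geometry lacks moment arm or reference length for {m.name}")
            arm = geometry.moment_arm[m.name]
            if m.group == "extensor" and arm <= 0:
                raise ValueError(f"extensor {m.name} must have a positive moment arm")
            if m.group == "flexor" and arm >= 0:
                raise ValueError(f"flexor {m.name} must have a negative moment arm")
        self.geometry = geometry
        self.muscles = list(muscles)
        self.tendon = tendon if tendon is not None else TendonConstants()
        self.iap = iap if iap is not None else IapParams()
        self.elastic_tendon = elastic_tendon
        self.gravity_on = gravity_on

    # ------------------------------------------------------------------ #
    def muscle(self, name: str) -> MuscleParams:
        for m in self.muscles:
            if m.name == name:
                return m
        raise KeyError(name)

    def set_f0_scale(self, group: str, scale: float) -> None:
        """Multiply F0 of every fascicle in a group by ``scale``."""
        self.muscles = [
            replace(m, f0=m.f0 * scale) if m.group == group else m for m in self.muscles
        ]

    def group_names(self, group: str) -> list[str]:
        return [m.name for m in self.muscles if m.group == group]

    # ------------------------------------------------------------------ #
    def mt_length(self, theta: float, name: str) -> float:
        """Muscle-tendon length (m) at flexion-positive angle theta (rad)."""
        m = self.muscle(name)
        lmt = self.geometry.mt_length_ref[name] + self.geometry.moment_arm[name] * theta
        if lmt <= m.tendon_slack * 0.5:
            raise ValueError(
                f"{name}: muscle-tendon length {lmt:.4f} m below half its tendon slack "
                f"length at theta={theta:.3f} rad"
            )
        return lmt

    def mt_velocity(self, omega: float, name: str) -> float:
        return self.geometry.moment_arm[name] * omega

    def gravity_moment(self, theta: float) -> float:
        """Extension-positive gravity moment: flexing the upright trunk
        produces a flexing (negative) moment."""
        if not self.gravity_on:
            return 0.0
        g = self.geometry
        return -g.trunk_mass * G * g.com_distance * math.sin(theta)

    def iap_moment(self, t: float, schedule: list[tuple[float, float, str]] | None) -> float:
        """Extension-positive IAP piston moment at time t.

        Pressure ramps linearly from 0 to peak over ``ramp_time`` at each
        phase onset, holds, and releases linearly over the final 0.5 s of
        the phase."""
        if schedule is None or self.iap.peak_pressure == 0.0:
            return 0.0
        for t0, t1, _phase in schedule:
            if t0 <= t < t1:
                rise = min(self.iap.ramp_time, t1 - t0)
                frac = min((t - t0) / rise, 1.0) if rise > 0 else 1.0
                release = min(0.5, t1 - t0)
                if t > t1 - release:
                    frac = min(frac, (t1 - t) / release)
                return self.iap.plateau_moment * frac
        return 0.0

    # ------------------------------------------------------------------ #
    def muscle_moment(self, theta: float, omega: float, activations: dict[str, float]) -> float:
        """Net extension-positive muscle moment at the joint."""
        total = 0.0
        for m in self.muscles:
            st = self.muscle_state(theta, omega, activations.get(m.name, 0.0), m.name)
            total += st.f_tend * self.geometry.moment_arm[m.name]
        return total

    def muscle_state(self, theta: float, omega: float, a: float, name: str) -> MuscleState:
        m = self.muscle(name)
        return muscle_tendon_force(
            a,
            self.mt_length(theta, name),
            self.mt_velocity(omega, name),
            m,
            self.tendon,
            elastic_tendon=self.elastic_tendon,
        )

    def net_moment(
        self,
        t: float,
        theta: float,
        omega: float,
        activations: dict[str, float],
        lever_angle: float,
        lever_rate: float,
        iap_schedule=None,
        extra_damping: float = 0.0,
    ) -> tuple[float, float]:
        """(total extension-positive moment, coupling moment)."""
        g = self.geometry
        m_coup = g.coupling_stiffness * (theta - lever_angle) + g.coupling_damping * (
            omega - lever_rate
        )
        total = (
            self.muscle_moment(theta, omega, activations)
            + self.gravity_moment(theta)
            + g.ivd_stiffness * theta
            + g.ivd_damping * omega
            + self.iap_moment(t, iap_schedule)
            + m_coup
            + extra_damping * omega
        )
        return total, m_coup

    def step_dynamics(
        self,
        state: PlantState,
        activations: dict[str, float],
        lever_fn,
        lever_rate_fn,
        dt: float = 1e-3,
        n_steps: int = 1,
        iap_schedule=None,
        extra_damping: float = 0.0,
    ) -> PlantState:
        """Advance the trunk by ``n_steps`` fixed RK4 steps of size dt with
        activations held constant; the lever angle is read from the
        prescribed trajectory callables."""
        if dt > 1e-3 + 1e-12:
            raise ValueError("internal integration step must be <= 1 ms")
        th, om, t = state.theta, state.omega, state.t
        inertia = self.geometry.trunk_inertia

        def deriv(ti, thi, omi):
            total, _ = self.net_moment(
                ti, thi, omi, activations, float(lever_fn(ti)), float(lever_rate_fn(ti)),
                iap_schedule, extra_damping,
            )
            return omi, -total / inertia

        for _ in range(n_steps):
            k1 = deriv(t, th, om)
            k2 = deriv(t + dt / 2, th + dt / 2 * k1[0], om + dt / 2 * k1[1])
            k3 = deriv(t + dt / 2, th + dt / 2 * k2[0], om + dt / 2 * k2[1])
            k4 = deriv(t + dt, th + dt * k3[0], om + dt * k3[1])
            th += dt / 6 * (k1[0] + 2 * k2[0] + 2 * k3[0] + k4[0])
            om += dt / 6 * (k1[1] + 2 * k2[1] + 2 * k3[1] + k4[1])
            t += dt
            if not (math.isfinite(th) and math.isfinite(om)):
                raise RuntimeError(f"trunk dynamics diverged at t={t:.3f} s")
        lever = float(lever_fn(t))
        _, m_coup = self.net_moment(
            t, th, om, activations, lever, float(lever_rate_fn(t)), iap_schedule, extra_damping
        )
        states = {
            m.name: self.muscle_state(th, om, activations.get(m.name, 0.0), m.name)
            for m in self.muscles
        }
        return PlantState(th, om, lever, m_coup, t=t, muscle_states=states)

    def initialize_posture(
        self,
        lever_angle: float,
        duration: float = 0.5,
        max_duration: float = 5.0,
        omega_tol: float = 1e-3,
    ) -> PlantState:
        """Dynamic relaxation to static equilibrium under gravity with
        passive muscles: the lever is held fixed and heavy artificial
        damping dissipates the transient.  Returns the settled state
        (time reset to 0)."""
        g = self.geometry
        k_tot = g.coupling_stiffness + g.ivd_stiffness
        c_relax = 2.0 * math.sqrt(k_tot * g.trunk_inertia)  # ~critical damping
        state = PlantState(lever_angle, 0.0, lever_angle, 0.0)
        acts = {m.name: 0.0 for m in self.muscles}
        lever = lambda t: lever_angle
        lever_rate = lambda t: 0.0
        t_sim, block = 0.0, 0.1
        while t_sim < max_duration:
            state = self.step_dynamics(
                state, acts, lever, lever_rate, dt=1e-3,
                n_steps=int(round(block / 1e-3)), extra_damping=c_relax,
            )
            t_sim += block
            if t_sim >= duration and abs(state.omega) < omega_tol:
                break
        else:
            raise RuntimeError(
                f"dynamic relaxation did not settle within {max_duration} s "
                f"(|omega|={abs(state.omega):.2e} rad/s)"
            )
        return PlantState(state.theta, state.omega, state.lever_angle, state.coupling_moment, t=0.0)

    def static_residual(self, state: PlantState) -> float:
        """Net joint moment (N m) at a candidate equilibrium."""
        acts = {m.name: 0.0 for m in self.muscles}
        total, _ = self.net_moment(
            0.0, state.theta, state.omega, acts, state.lever_angle, 0.0
        )
        return total
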