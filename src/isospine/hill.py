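"""Hill-type muscle-tendon element.

The contractile element (CE) produces the active force, the parallel
elastic element (PE) the passive fiber force, and the series elastic
element (SE, the tendon) transmits both to the skeleton.  For a pennate
fiber at angle ``alpha`` the quasi-static equilibrium is

    (F_CE + F_PE) * cos(alpha) = F_tend

with F_CE = a * F0 * f_l(l/l0) * f_v(ldot/v0).  The curve shapes follow
the Thelen-style phenomenological forms: a Gaussian-like active
force-length curve peaking at l/l0 = 19/20, an arctangent force-velocity
curve saturating in eccentric lengthening, a cubic passive curve engaging
above optimal length, and an exponential-toe / linear tendon curve.

Sign convention: fiber velocity is positive when lengthening, so the
force-velocity factor is zero for fast shortening (ldot < -v0).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from scipy.optimize import brentq

__all__ = [
    "ActivationParams",
    "MuscleParams",
    "TendonConstants",
    "MuscleState",
    "activation_step",
    "force_length_factor",
    "force_velocity_factor",
    "passive_force",
    "tendon_force",
    "muscle_tendon_force",
]

#: force-velocity eccentric plateau value, pi/(4*arctan 5) + 1
FV_MAX = math.pi / (4.0 * math.atan(5.0)) + 1.0

#: normalized fiber length at which the active force-length curve peaks
L_NORM_OPT = 19.0 / 20.0


@dataclass(frozen=True)
class ActivationParams:
    """First-order activation dynamics time constants (seconds)."""

    tau_act: float = 0.010
    tau_deact: float = 0.040

    def __post_init__(self) -> None:
        if not (self.tau_act > 0 and self.tau_deact > 0):
            raise ValueError("activation time constants must be positive")
        if self.tau_deact < self.tau_act:
            raise ValueError("tau_deact must be >= tau_act")


@dataclass(frozen=True)
class TendonConstants:
    """Dimensionless tendon curve constants.

    ``eps_toe`` (the strain ending the exponential toe region) is derived
    from the strain at maximum isometric force, eps_toe = 0.609 * eps0.
    """

    f_toe: float = 0.33
    k_toe: float = 3.0
    k_lin: float = 42.8

    def eps_toe(self, eps0: float) -> float:
        return 0.609 * eps0


@dataclass
class MuscleParams:
    """Per-fascicle Hill/tendon parameters.

    Parameters
    ----------
    f0 : maximum isometric force, N (the identification target)
    l0 : optimal fiber length, m
    v0 : maximum contraction velocity, m/s
    alpha : pennation angle, rad
    tendon_slack : tendon slack length, m
    eps0 : tendon strain at F0, dimensionless
    pcsa : physiological cross-sectional area, cm^2
    group : "flexor", "extensor" or "breathing"
    """

    name: str
    group: str
    f0: float
    l0: float
    v0: float
    alpha: float = 0.0
    tendon_slack: float = 0.0
    eps0: float = 0.04
    pcsa: float = 10.0

    def __post_init__(self) -> None:
        if self.group not in ("flexor", "extensor", "breathing"):
            raise ValueError(f"unknown muscle group {self.group!r}")
        if not (self.f0 > 0 and self.l0 > 0 and self.v0 > 0):
            raise ValueError(f"{self.name}: f0, l0, v0 must be positive")
        if not (0.0 <= self.alpha < math.pi / 2):
            raise ValueError(f"{self.name}: pennation angle out of [0, pi/2)")
        if not (self.pcsa > 0 and self.eps0 > 0):
            raise ValueError(f"{self.name}: pcsa and eps0 must be positive")
        if self.tendon_slack < 0:
            raise ValueError(f"{self.name}: tendon slack length must be >= 0")


@dataclass
class MuscleState:
    """Instantaneous muscle-tendon state (forces in N, lengths in m)."""

    a: float
    l: float
    ldot: float
    f_ce: float
    f_pe: float
    f_tend: float
    eps_tend: float


def activation_step(a: float, u: float, params: ActivationParams, dt: float) -> float:
    """Advance activation one forward-Euler step of the activation ODE.

    da/dt = (u - a) / tau_a(a, u), where the characteristic time is
    tau_act*(0.5 + 1.5 a) when the stimulus exceeds the activation
    (recruitment) and tau_deact/(0.5 + 1.5 a) otherwise (derecruitment).
    The result is clipped to [0, 1].
    """
    if not (math.isfinite(a) and math.isfinite(u)):
        raise ValueError("activation_step: non-finite input")
    if dt <= 0:
        raise ValueError("activation_step: dt must be positive")
    if u > a:
        tau = params.tau_act * (0.5 + 1.5 * a)
    else:
        tau = params.tau_deact / (0.5 + 1.5 * a)
    a_next = a + dt * (u - a) / tau
    return min(1.0, max(0.0, a_next))


def force_length_factor(l_norm: float) -> float:
    """Active force-length scaling f_l = exp(-x^4 - x^2), x = (9/4)(l/l0 - 19/20)."""
    if not math.isfinite(l_norm) or l_norm <= 0:
        raise ValueError("force_length_factor: l_norm must be positive and finite")
    x = 2.25 * (l_norm - L_NORM_OPT)
    return math.exp(-(x ** 4) - x ** 2)


def force_velocity_factor(ldot: float, v0: float) -> float:
    """Force-velocity scaling (lengthening positive).

    Zero for fast shortening (ldot < -v0), arctan(5*ldot/v0)/arctan(5) + 1
    in the working range, and the eccentric plateau pi/(4 arctan 5) + 1
    for ldot > 0.2*v0.  Continuous at both joins.
    """
    if v0 <= 0:
        raise ValueError("force_velocity_factor: v0 must be positive")
    r = ldot / v0
    if r < -1.0:
        return 0.0
    if r > 0.2:
        return FV_MAX
    return math.atan(5.0 * r) / math.atan(5.0) + 1.0


def passive_force(l: float, params: MuscleParams) -> float:
    """Parallel-elastic fiber force: engages above optimal length.

    0 below l0; 8*F0*(l/l0 - 1)^3 up to 1.63*l0; saturates at 2*F0.
    """
    if l <= 0:
        raise ValueError("passive_force: fiber length must be positive")
    r = l / params.l0
    if r < 1.0:
        return 0.0
    if r > 1.63:
        return 2.0 * params.f0
    return 8.0 * params.f0 * (r - 1.0) ** 3


def tendon_force(eps: float, params: MuscleParams, tc: TendonConstants | None = None) -> float:
    """Series-elastic (tendon) force as a function of tendon strain.

    Exponential toe region up to eps_toe = 0.609*eps0, linear above with
    dimensionless stiffness k_lin; slack (eps < 0) transmits no force.
    """
    tc = tc if tc is not None else TendonConstants()
    if eps <= 0:
        return 0.0
    eps_toe = tc.eps_toe(params.eps0)
    if eps <= eps_toe:
        return (
            params.f0
            * tc.f_toe
            * (math.expm1(tc.k_toe * eps / eps_toe))
            / (math.expm1(tc.k_toe))
        )
    return params.f0 * (tc.k_lin * (eps - eps_toe) + tc.f_toe)


def _rigid_tendon_state(
    a: float, mt_length: float, mt_velocity: float, params: MuscleParams
) -> MuscleState:
    cos_a = math.cos(params.alpha)
    l = (mt_length - params.tendon_slack) / cos_a
    ldot = mt_velocity / cos_a
    if l <= 0:
        # fiber fully slack; transmit nothing
        return MuscleState(a, max(l, 0.0), ldot, 0.0, 0.0, 0.0, 0.0)
    f_ce = a * params.f0 * force_length_factor(l / params.l0) * force_velocity_factor(ldot, params.v0)
    f_pe = passive_force(l, params)
    f_tend = (f_ce + f_pe) * cos_a
    return MuscleState(a, l, ldot, f_ce, f_pe, f_tend, 0.0)


def muscle_tendon_force(
    a: float,
    mt_length: float,
    mt_velocity: float,
    params: MuscleParams,
    tc: TendonConstants | None = None,
    elastic_tendon: bool = False,
    rel_tol: float = 1e-6,
) -> MuscleState:
    """Resolve the fiber-tendon force equilibrium for one fascicle.

    In the default rigid-tendon mode the tendon keeps its slack length and
    the fiber absorbs all muscle-tendon kinematics.  In elastic mode the
    fiber length is found by a scalar root solve of
    (F_CE + F_PE) cos(alpha) = F_tend(eps) with
    eps = (mt_length - l*cos(alpha) - slack) / slack.
    """
    tc = tc if tc is not None else TendonConstants()
    if mt_length <= params.tendon_slack * 0.5:
        raise ValueError(
            f"muscle {params.name}: muscle-tendon length {mt_length:.4f} m "
            "shorter than half the tendon slack length"
        )
    if not elastic_tendon or params.tendon_slack == 0.0:
        return _rigid_tendon_state(a, mt_length, mt_velocity, params)

    cos_a = math.cos(params.alpha)

    def residual(l: float) -> float:
        eps = (mt_length - l * cos_a - params.tendon_slack) / params.tendon_slack
        f_ce = a * params.f0 * force_length_factor(l / params.l0) * force_velocity_factor(
            mt_velocity / cos_a, params.v0
        )
        f_pe = passive_force(l, params)
        return (f_ce + f_pe) * cos_a - tendon_force(eps, params, tc)

    lo = 1e-4 * params.l0
    hi = (mt_length - 1e-9) / cos_a
    f_lo, f_hi = residual(lo), residual(hi)
    if f_lo * f_hi > 0:
        raise RuntimeError(
            f"muscle {params.name}: no fiber-tendon equilibrium root in bracket "
            f"[{lo:.4g}, {hi:.4g}] m"
        )
    l = brentq(residual, lo, hi, xtol=1e-12, rtol=8.9e-16)
    eps = (mt_length - l * cos_a - params.tendon_slack) / params.tendon_slack
    ldot = mt_velocity / cos_a
    f_ce = a * params.f0 * force_length_factor(l / params.l0) * force_velocity_factor(ldot, params.v0)
    f_pe = passive_force(l, params)
    f_tend = tendon_force(eps, params, tc)
    if abs((f_ce + f_pe) * cos_a - f_tend) > rel_tol * params.f0:
        raise RuntimeError(f"muscle {params.name}: equilibrium residual above tolerance")
    return MuscleState(a, l, ldot, f_ce, f_pe, f_tend, eps)
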