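"""Isokinetic trial simulation and maximum-isometric-force calibration.

A proportional-derivative activation controller drives the trunk plant to
track the prescribed (or measured) dynamometer angle.  The controller is
incremental: at every 10-ms control step the command of fascicle m in
group g is incremented by

    (PCSA_m / sum_i PCSA_i) * (kp * e~ + kd * de~/dt)

where e~ is the extension-positive tracking error evaluated against a
0.5-s preview of the reference trajectory (neural prediction of future
motion); a positive command activates the extensors, a negative one the
flexors, with the antagonist group resting at the 0.02 activation floor
unless synergy coupling raises it.  Activations are clipped to
[0.02, 1].

The simulated isokinetic moment is M_isom = M_act - M_deact, the
difference between the constraint (coupling) moments of an actively
controlled run and a passive run, which cancels gravity, bushing and
passive-muscle contributions the dynamometer's gravity compensation also
removes.  Strength calibration iterates forward simulations, comparing
the measured and simulated peak moments through the ratios

    beta_ext = max(M_exp) / max(M_sim),   beta_flex = min(M_exp) / min(M_sim)

and multiplying every fascicle F0 of an out-of-band group by its beta
until both ratios fall inside [1 - delta, 1 + delta].
"""

from __future__ import annotations

import copy
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sig
from scipy import stats
from sklearn.base import BaseEstimator

from .hill import FV_MAX
from .plant import IsokineticProtocol, TrunkPlant
from .synergy import SynergyCoupling
from .trace import MomentTrace, avg_first_extrema, segment_phases

__all__ = [
    "ControllerParams",
    "PDController",
    "TrialResult",
    "CalibrationConfig",
    "CalibrationResult",
    "MetricsReport",
    "StrengthIdentifier",
    "simulate_trial",
    "simulate_isokinetic_moment",
    "calibrate_strength",
    "personalize_fiber_length",
    "metrics",
]

_INV_ATAN5 = 1.0 / math.atan(5.0)


@dataclass(frozen=True)
class ControllerParams:
    """PD activation controller constants."""

    kp: float = 0.05
    kd: float = 5.0
    dt: float = 0.01  # control step, s
    tau_preview: float = 0.5  # feedforward time, s
    a_min: float = 0.02
    a_max: float = 1.0
    feedforward: str = "preview"  # or "delay": literal tau-delayed error

    def __post_init__(self) -> None:
        if self.kp < 0 or self.kd < 0 or self.dt <= 0:
            raise ValueError("kp, kd must be >= 0 and dt > 0")
        if not self.a_min < self.a_max:
            raise ValueError("a_min must be below a_max")
        if self.feedforward not in ("preview", "delay"):
            raise ValueError("feedforward must be 'preview' or 'delay'")


class PDController:
    """Incremental PD activation controller over grouped fascicles."""

    def __init__(
        self,
        params: ControllerParams,
        plant: TrunkPlant,
        coupling: SynergyCoupling | None = None,
        with_synergy: bool = False,
    ) -> None:
        if with_synergy and coupling is None:
            raise ValueError("synergy coupling requested but no coupling provided")
        self.params = params
        self.coupling = coupling
        self.with_synergy = with_synergy
        self.names = [m.name for m in plant.muscles if m.group in ("extensor", "flexor")]
        self.groups = {m.name: m.group for m in plant.muscles}
        pcsa = {m.name: m.pcsa for m in plant.muscles}
        group_tot = {
            g: sum(pcsa[n] for n in self.names if self.groups[n] == g)
            for g in ("extensor", "flexor")
        }
        self.share = {n: pcsa[n] / group_tot[self.groups[n]] for n in self.names}
        self.pcsa = pcsa
        self.reset()

    def reset(self) -> None:
        self.command = {n: 0.0 for n in self.names}
        self._eref_prev: float | None = None
        self._history: list[float] = []

    def _errors(self, t: float, ref_angle, theta_sim: float, t_end: float) -> tuple[float, float]:
        """(preview error e~, reference-side error for differentiation), rad.

        The derivative channel is evaluated along the reference trajectory
        (perfect-tracking approximation, theta_sim -> theta_ref(t)): the
        incremental form multiplies kd * de~/dt by the control rate, so
        differentiating the raw error would feed the compliant
        trunk-lever coupling's resonance back at high gain and chatter;
        the reference-side derivative keeps only the anticipatory
        phase-reversal signal the feedforward time is meant to provide.
        """
        p = self.params
        if p.feedforward == "preview":
            t_ref = min(t + p.tau_preview, t_end)
            e = theta_sim - float(ref_angle(t_ref))
            e_ref = float(ref_angle(min(t, t_end))) - float(ref_angle(t_ref))
            return e, e_ref
        # literal tau-delayed raw error
        e_now = theta_sim - float(ref_angle(t))
        self._history.append(e_now)
        lag = int(round(p.tau_preview / p.dt))
        e = self._history[-lag - 1] if len(self._history) > lag else 0.0
        return e, e

    def update(
        self, t: float, ref_angle, theta_sim: float, t_end: float, phase: str | None = None
    ) -> dict[str, float]:
        """Advance one control step; returns per-fascicle activations."""
        p = self.params
        e, e_ref = self._errors(t, ref_angle, theta_sim, t_end)
        dedt = 0.0 if self._eref_prev is None else (e_ref - self._eref_prev) / p.dt
        self._eref_prev = e_ref
        pd = p.kp * e + p.kd * dedt
        acts: dict[str, float] = {}
        for n in self.names:
            c = self.command[n] + self.share[n] * pd
            self.command[n] = c
            g = self.groups[n]
            if g == "extensor":
                a = c if c > 0 else 0.0
            else:
                a = -c if c < 0 else 0.0
            acts[n] = min(p.a_max, max(p.a_min, a))
        if self.with_synergy and phase in ("Ext", "Flx"):
            agonist = "extensor" if phase == "Ext" else "flexor"
            antagonist = "flexor" if phase == "Ext" else "extensor"
            ratio = (
                self.coupling.ratio_flexor_during_ext
                if phase == "Ext"
                else self.coupling.ratio_extensor_during_flx
            )
            ag = [n for n in self.names if self.groups[n] == agonist]
            a_g = sum(acts[n] * self.pcsa[n] for n in ag) / sum(self.pcsa[n] for n in ag)
            a_ant = min(1.0, max(p.a_min, ratio * a_g))
            for n in self.names:
                if self.groups[n] == antagonist:
                    acts[n] = max(acts[n], a_ant)
        return acts


@dataclass
class TrialResult:
    """Simulation output at the control rate."""

    trace: MomentTrace  # moment = recorded constraint moment; angle = trunk angle
    lever_angle_deg: np.ndarray
    activations: dict[str, np.ndarray]
    fiber_length: dict[str, np.ndarray]


@dataclass
class CalibrationConfig:
    delta: float = 0.2
    max_iters: int = 10
    with_synergy: bool = False
    with_iap: bool = False

    def __post_init__(self) -> None:
        if not 0.0 < self.delta < 1.0:
            raise ValueError("delta must lie in (0, 1)")


@dataclass
class CalibrationResult:
    beta_ext: list[float]
    beta_flex: list[float]
    f0_scale_ext: list[float]
    f0_scale_flex: list[float]
    f0_final: dict[str, float]
    converged: bool
    n_iter: int
    percent_error_ext: float
    percent_error_flex: float
    pearson_r: float
    rmse_angle_deg: float


@dataclass
class MetricsReport:
    percent_error_ext: float
    percent_error_flex: float
    pearson_r: float
    rmse_angle_deg: float


# ---------------------------------------------------------------------- #
#  trial simulation
# ---------------------------------------------------------------------- #


def _lever_functions(lever, plant: TrunkPlant):
    """Normalize the lever specification to (angle_fn, rate_fn, t_end) in
    flexion-positive radians; accepts an IsokineticProtocol or a measured
    MomentTrace."""
    if isinstance(lever, IsokineticProtocol):
        ang = lambda t: math.radians(float(lever.angle_deg(t)))
        rate = lambda t: math.radians(float(lever.rate_deg(t)))
        return ang, rate, lever.duration
    if isinstance(lever, MomentTrace):
        t = lever.time - lever.time[0]
        th = np.radians(lever.angle_deg)
        om = np.gradient(th, t)
        ang = lambda ti: float(np.interp(ti, t, th))
        rate = lambda ti: float(np.interp(ti, t, om))
        return ang, rate, float(t[-1])
    raise TypeError("lever must be an IsokineticProtocol or a measured MomentTrace")


def simulate_trial(
    plant: TrunkPlant,
    lever,
    controller: PDController | None = None,
    passive: bool = False,
    with_iap: bool = False,
    dt_internal: float = 1e-3,
    init_state=None,
    iap_schedule=None,
) -> TrialResult:
    """Forward-simulate one isokinetic trial.

    The controller output is held (zero-order) over each 10-ms control
    step while the plant integrates at 1-ms RK4 steps.  A passive run
    switches the controller off and holds all activations at exactly zero
    (the 0.02 floor is a controller output constraint, not a muscle
    property).  Returns the recorded constraint moment, the simulated
    trunk angle, and per-fascicle activation/fiber-length histories at
    the control rate.
    """
    ref_angle, ref_rate, t_end = _lever_functions(lever, plant)
    dt_c = controller.params.dt if controller is not None else 0.01
    n_sub = int(round(dt_c / dt_internal))
    if n_sub < 1 or abs(n_sub * dt_internal - dt_c) > 1e-12:
        raise ValueError("control step must be an integer multiple of the internal step")
    n_ctrl = int(round(t_end / dt_c))

    if iap_schedule is None and with_iap:
        if isinstance(lever, IsokineticProtocol):
            iap_schedule = lever.phase_intervals()
        else:
            iap_schedule = _schedule_from_angle(lever)

    if init_state is None:
        init_state = plant.initialize_posture(ref_angle(0.0))
    if controller is not None:
        controller.reset()

    if plant.elastic_tendon:
        return _simulate_generic(
            plant, controller, passive, ref_angle, ref_rate, t_end, dt_c, n_sub,
            dt_internal, n_ctrl, init_state, iap_schedule if with_iap else None,
        )
    return _simulate_fast(
        plant, controller, passive, ref_angle, ref_rate, t_end, dt_c, n_sub,
        dt_internal, n_ctrl, init_state, iap_schedule if with_iap else None,
    )


def _schedule_from_angle(trace: MomentTrace):
    t = trace.time - trace.time[0]
    out = []
    for s, phase in segment_phases(t, trace.angle_deg):
        out.append((float(t[s][0]), float(t[s][-1]), phase))
    return out


def _phase_at(ref_rate, t: float) -> str:
    return "Ext" if ref_rate(t) < 0 else "Flx"


def _simulate_fast(
    plant, controller, passive, ref_angle, ref_rate, t_end, dt_c, n_sub,
    dt_i, n_ctrl, init_state, iap_schedule,
):
    geom = plant.geometry
    muscles = plant.muscles
    nm = len(muscles)
    arm = [geom.moment_arm[m.name] for m in muscles]
    ref_l = [geom.mt_length_ref[m.name] for m in muscles]
    f0 = [m.f0 for m in muscles]
    l0 = [m.l0 for m in muscles]
    v0 = [m.v0 for m in muscles]
    slack = [m.tendon_slack for m in muscles]
    cos_a = [math.cos(m.alpha) for m in muscles]
    inv_cos = [1.0 / c for c in cos_a]
    names = [m.name for m in muscles]

    kc, cc = geom.coupling_stiffness, geom.coupling_damping
    kivd, civd = geom.ivd_stiffness, geom.ivd_damping
    mgd = geom.trunk_mass * 9.81 * geom.com_distance if plant.gravity_on else 0.0
    inertia = geom.trunk_inertia

    # lever angle/rate and IAP moment precomputed on the half-step grid
    n_i = n_ctrl * n_sub
    t_half = np.arange(2 * n_i + 1) * (dt_i / 2.0)
    lt = np.array([ref_angle(ti) for ti in t_half])
    lo_ = np.array([ref_rate(ti) for ti in t_half])
    miap = np.array([plant.iap_moment(ti, iap_schedule) for ti in t_half])

    sin = math.sin
    exp = math.exp
    atan = math.atan

    def deriv(j, th, om, acts):
        msum = 0.0
        for i in range(nm):
            l = (ref_l[i] + arm[i] * th - slack[i]) * inv_cos[i]
            if l <= 0.0:
                continue
            rl = l / l0[i]
            x = 2.25 * (rl - 0.95)
            x2 = x * x
            fl = exp(-x2 * x2 - x2)
            r = arm[i] * om * inv_cos[i] / v0[i]
            if r < -1.0:
                fv = 0.0
            elif r > 0.2:
                fv = FV_MAX
            else:
                fv = atan(5.0 * r) * _INV_ATAN5 + 1.0
            if rl < 1.0:
                fpe = 0.0
            elif rl > 1.63:
                fpe = 2.0 * f0[i]
            else:
                d = rl - 1.0
                fpe = 8.0 * f0[i] * d * d * d
            msum += (acts[i] * f0[i] * fl * fv + fpe) * cos_a[i] * arm[i]
        mcoup = kc * (th - lt[j]) + cc * (om - lo_[j])
        total = msum - mgd * sin(th) + kivd * th + civd * om + miap[j] + mcoup
        return om, -total / inertia, mcoup

    th, om = init_state.theta, init_state.omega
    if not passive and controller is not None:
        # pre-roll over the feedforward window: the subject is braced and
        # pushing before the lever starts moving
        n_pre = int(round(controller.params.tau_preview / dt_c))
        for k in range(-n_pre, 0):
            controller.update(k * dt_c, ref_angle, th, t_end, None)
    rec_t = np.empty(n_ctrl + 1)
    rec_th = np.empty(n_ctrl + 1)
    rec_m = np.empty(n_ctrl + 1)
    rec_a = np.zeros((nm, n_ctrl + 1))
    rec_l = np.zeros((nm, n_ctrl + 1))
    acts = [0.0] * nm

    h = dt_i
    for k in range(n_ctrl + 1):
        t = k * dt_c
        j = 2 * k * n_sub
        if not passive and controller is not None:
            adict = controller.update(t, ref_angle, th, t_end, _phase_at(ref_rate, t))
            acts = [adict.get(n, 0.0) for n in names]
        _, _, mcoup = deriv(j, th, om, acts)
        rec_t[k], rec_th[k], rec_m[k] = t, th, -mcoup
        for i in range(nm):
            rec_a[i, k] = acts[i]
            rec_l[i, k] = (ref_l[i] + arm[i] * th - slack[i]) * inv_cos[i]
        if k == n_ctrl:
            break
        for s in range(n_sub):
            jj = j + 2 * s
            d1 = deriv(jj, th, om, acts)
            d2 = deriv(jj + 1, th + 0.5 * h * d1[0], om + 0.5 * h * d1[1], acts)
            d3 = deriv(jj + 1, th + 0.5 * h * d2[0], om + 0.5 * h * d2[1], acts)
            d4 = deriv(jj + 2, th + h * d3[0], om + h * d3[1], acts)
            th += h / 6.0 * (d1[0] + 2.0 * d2[0] + 2.0 * d3[0] + d4[0])
            om += h / 6.0 * (d1[1] + 2.0 * d2[1] + 2.0 * d3[1] + d4[1])
        if not (math.isfinite(th) and math.isfinite(om)):
            raise RuntimeError(f"trial simulation diverged at t={t:.3f} s")

    kind = "simulated_passive" if passive else "simulated_active"
    trace = MomentTrace(rec_t, np.degrees(rec_th), rec_m, kind=kind)
    return TrialResult(
        trace,
        lever_angle_deg=np.degrees(lt[:: 2 * n_sub]),
        activations={n: rec_a[i] for i, n in enumerate(names)},
        fiber_length={n: rec_l[i] for i, n in enumerate(names)},
    )


def _simulate_generic(
    plant, controller, passive, ref_angle, ref_rate, t_end, dt_c, n_sub,
    dt_i, n_ctrl, init_state, iap_schedule,
):
    """Reference path through TrunkPlant.step_dynamics (used for elastic
    tendons); slower but mode-complete."""
    from .plant import PlantState

    names = [m.name for m in plant.muscles]
    state = PlantState(
        init_state.theta, init_state.omega, init_state.lever_angle,
        init_state.coupling_moment, t=0.0,
    )
    acts = {n: 0.0 for n in names}
    rec_t, rec_th, rec_m = [], [], []
    rec_a = {n: [] for n in names}
    rec_l = {n: [] for n in names}

    def record(st, acts):
        rec_t.append(st.t)
        rec_th.append(st.theta)
        rec_m.append(-st.coupling_moment)
        for n in names:
            rec_a[n].append(acts[n])
            rec_l[n].append(st.muscle_states[n].l if st.muscle_states else float("nan"))

    if not passive and controller is not None:
        n_pre = int(round(controller.params.tau_preview / dt_c))
        for k in range(-n_pre, 0):
            controller.update(k * dt_c, ref_angle, state.theta, t_end, None)
    _, mcoup = plant.net_moment(
        0.0, state.theta, state.omega, acts, float(ref_angle(0.0)), float(ref_rate(0.0)),
        iap_schedule,
    )
    state.coupling_moment = mcoup
    state.muscle_states = {
        n: plant.muscle_state(state.theta, state.omega, acts[n], n) for n in names
    }
    record(state, acts)
    for k in range(n_ctrl):
        t = k * dt_c
        if not passive and controller is not None:
            acts = controller.update(t, ref_angle, state.theta, t_end, _phase_at(ref_rate, t))
            acts = {n: acts.get(n, 0.0) for n in names}
        state = plant.step_dynamics(
            state, acts, ref_angle, ref_rate, dt=dt_i, n_steps=n_sub,
            iap_schedule=iap_schedule,
        )
        record(state, acts)
    trace = MomentTrace(
        np.array(rec_t), np.degrees(rec_th), np.array(rec_m),
        kind="simulated_passive" if passive else "simulated_active",
    )
    lever = np.degrees([ref_angle(ti) for ti in rec_t])
    return TrialResult(
        trace, lever, {n: np.array(v) for n, v in rec_a.items()},
        {n: np.array(v) for n, v in rec_l.items()},
    )


def simulate_isokinetic_moment(
    plant: TrunkPlant,
    lever,
    controller: PDController,
    with_iap: bool = False,
    init_state=None,
    filter_hz: float | None = None,
) -> tuple[MomentTrace, TrialResult, TrialResult]:
    """Run the active and passive trials and return M_isom = M_act - M_deact
    together with both raw runs.

    ``filter_hz`` optionally applies the fourth-order zero-phase
    Butterworth low-pass used on measured dynamometer curves; it is off
    by default because the zero-phase filter's undershoot after the broad
    extension plateau can masquerade as a flexion peak, whereas the raw
    simulated difference is already smooth.
    """
    if init_state is None:
        ref_angle, _, _ = _lever_functions(lever, plant)
        init_state = plant.initialize_posture(ref_angle(0.0))
    active = simulate_trial(
        plant, lever, controller, passive=False, with_iap=with_iap, init_state=init_state
    )
    passive = simulate_trial(plant, lever, None, passive=True, init_state=init_state)
    moment = active.trace.moment - passive.trace.moment
    if filter_hz is not None:
        fs = 1.0 / float(np.mean(np.diff(active.trace.time)))
        sos = sig.butter(4, filter_hz / (fs / 2.0), btype="lowpass", output="sos")
        moment = sig.sosfiltfilt(sos, moment)
    misom = MomentTrace(active.trace.time, active.trace.angle_deg, moment, kind="isom")
    return misom, active, passive


# ---------------------------------------------------------------------- #
#  metrics and calibration
# ---------------------------------------------------------------------- #


def metrics(
    measured: MomentTrace,
    simulated: MomentTrace,
    n_peaks: int = 3,
) -> MetricsReport:
    """Error and correlation report between a measured and a simulated trial.

    Percent error per muscle group is the relative difference of the
    averages of the first ``n_peaks`` per-cycle moment extrema (extension
    maxima for the extensors, flexion minima for the flexors), in percent
    of the measured value.  Pearson r is computed over the full common
    time base; the angle RMSE compares the simulated trunk angle with the
    measured (prescribed) angle.
    """
    t = measured.time
    sim_m = simulated.resample_moment(t)
    sim_a = simulated.resample_angle(t)
    n_ext = sum(1 for _, p in segment_phases(t, measured.angle_deg) if p == "Ext")
    if n_ext < n_peaks:
        warnings.warn(
            f"only {n_ext} extension cycles available; averaging over those", stacklevel=2
        )
    meas_ext = avg_first_extrema(t, measured.angle_deg, measured.moment, "Ext", n_peaks)
    meas_flx = avg_first_extrema(t, measured.angle_deg, measured.moment, "Flx", n_peaks)
    sim_ext = avg_first_extrema(t, measured.angle_deg, sim_m, "Ext", n_peaks)
    sim_flx = avg_first_extrema(t, measured.angle_deg, sim_m, "Flx", n_peaks)
    err_ext = 100.0 * abs(sim_ext - meas_ext) / abs(meas_ext)
    err_flx = 100.0 * abs(sim_flx - meas_flx) / abs(meas_flx)
    r = float(stats.pearsonr(measured.moment, sim_m).statistic)
    rmse = float(np.sqrt(np.mean((sim_a - measured.angle_deg) ** 2)))
    return MetricsReport(err_ext, err_flx, r, rmse)


class StrengthIdentifier(BaseEstimator):
    """Iterative maximum-isometric-force calibration (sklearn estimator).

    ``fit(measured)`` repeatedly simulates the isokinetic trial on a deep
    copy of the plant, compares peak moments through the beta ratios, and
    rescales the flexor/extensor F0 until both ratios fall within
    [1 - delta, 1 + delta] or ``max_iters`` is reached.

    Attributes (after fit)
    ----------------------
    plant_ : calibrated plant copy
    f0_ : final F0 per fascicle, N
    beta_ext_, beta_flex_ : per-iteration beta ratios
    f0_scale_ext_, f0_scale_flex_ : cumulative F0 scale factors applied
    converged_ : True when both ratios ended inside the band
    result_ : CalibrationResult with the final error metrics
    """

    def __init__(
        self,
        plant: TrunkPlant | None = None,
        controller: ControllerParams | None = None,
        delta: float = 0.2,
        max_iters: int = 10,
        with_synergy: bool = False,
        with_iap: bool = False,
        coupling: SynergyCoupling | None = None,
        personalize: bool = False,
    ) -> None:
        self.plant = plant
        self.controller = controller
        self.delta = delta
        self.max_iters = max_iters
        self.with_synergy = with_synergy
        self.with_iap = with_iap
        self.coupling = coupling
        self.personalize = personalize

    def _simulate(self, plant, measured, init_state):
        ctrl = PDController(
            self.controller or ControllerParams(), plant,
            coupling=self.coupling, with_synergy=self.with_synergy,
        )
        return simulate_isokinetic_moment(
            plant, measured, ctrl, with_iap=self.with_iap, init_state=init_state
        )

    def fit(self, X: MomentTrace, y=None):
        measured = X
        if self.plant is None:
            raise ValueError("StrengthIdentifier requires a plant")
        n_cycles = sum(
            1 for _, p in segment_phases(measured.time, measured.angle_deg) if p == "Ext"
        )
        if n_cycles < 3:
            warnings.warn(
                f"measured trace covers only {n_cycles} cycles (>= 3 recommended)",
                stacklevel=2,
            )
        plant = copy.deepcopy(self.plant)
        ref_angle, _, _ = _lever_functions(measured, plant)
        init_state = plant.initialize_posture(ref_angle(0.0))
        delta = self.delta

        beta_ext_hist: list[float] = []
        beta_flex_hist: list[float] = []
        scale_ext_hist: list[float] = []
        scale_flex_hist: list[float] = []
        scale_ext = scale_flex = 1.0
        converged = False
        misom = active = None
        # peak moments as the trial's representative extension maximum and
        # flexion minimum: the mean of the first three per-cycle extrema of
        # the matching movement phase (the statistic the error metric and
        # the reported maximum-moment values use), which keeps the beta
        # ratios phase-consistent — the anticipatory activation switch just
        # before a reversal cannot masquerade as the opposite-phase peak —
        # and robust to single-cycle noise
        t_m, a_m = measured.time, measured.angle_deg
        meas_max = avg_first_extrema(t_m, a_m, measured.moment, "Ext")
        meas_min = avg_first_extrema(t_m, a_m, measured.moment, "Flx")

        for it in range(self.max_iters):
            misom, active, _ = self._simulate(plant, measured, init_state)
            sim_m = misom.resample_moment(t_m)
            sim_max = avg_first_extrema(t_m, a_m, sim_m, "Ext")
            sim_min = avg_first_extrema(t_m, a_m, sim_m, "Flx")
            if sim_max <= 0 or sim_min >= 0:
                raise RuntimeError(
                    "degenerate simulation: simulated moment lacks an extension "
                    "maximum or flexion minimum"
                )
            b_ext = meas_max / sim_max
            b_flex = meas_min / sim_min
            beta_ext_hist.append(b_ext)
            beta_flex_hist.append(b_flex)
            ok_ext = 1.0 - delta <= b_ext <= 1.0 + delta
            ok_flex = 1.0 - delta <= b_flex <= 1.0 + delta
            if ok_ext and ok_flex:
                converged = True
                scale_ext_hist.append(scale_ext)
                scale_flex_hist.append(scale_flex)
                break
            if not ok_ext:
                plant.set_f0_scale("extensor", b_ext)
                scale_ext *= b_ext
            if not ok_flex:
                plant.set_f0_scale("flexor", b_flex)
                scale_flex *= b_flex
            scale_ext_hist.append(scale_ext)
            scale_flex_hist.append(scale_flex)

        if self.personalize and converged:
            plant = personalize_fiber_length(
                active, misom, plant, muscles=("ES", "RA")
            )
            misom, active, _ = self._simulate(plant, measured, init_state)

        rep = metrics(measured, misom)
        sim_angle = MomentTrace(
            active.trace.time, active.trace.angle_deg, active.trace.moment,
            kind="simulated_active",
        )
        rmse = float(
            np.sqrt(
                np.mean(
                    (sim_angle.resample_angle(measured.time) - measured.angle_deg) ** 2
                )
            )
        )
        self.plant_ = plant
        self.f0_ = {m.name: m.f0 for m in plant.muscles}
        self.beta_ext_ = beta_ext_hist
        self.beta_flex_ = beta_flex_hist
        self.f0_scale_ext_ = scale_ext_hist
        self.f0_scale_flex_ = scale_flex_hist
        self.converged_ = converged
        self.n_iter_ = len(beta_ext_hist)
        self.misom_ = misom
        self.active_ = active
        self.result_ = CalibrationResult(
            beta_ext=beta_ext_hist,
            beta_flex=beta_flex_hist,
            f0_scale_ext=scale_ext_hist,
            f0_scale_flex=scale_flex_hist,
            f0_final=self.f0_,
            converged=converged,
            n_iter=self.n_iter_,
            percent_error_ext=rep.percent_error_ext,
            percent_error_flex=rep.percent_error_flex,
            pearson_r=rep.pearson_r,
            rmse_angle_deg=rmse,
        )
        return self

    def predict(self, X: MomentTrace) -> MomentTrace:
        """Simulate M_isom on a (possibly different) measured trial with the
        calibrated plant."""
        misom, *_ = self._simulate_with(self.plant_, X)
        return misom

    def _simulate_with(self, plant, measured):
        ref_angle, _, _ = _lever_functions(measured, plant)
        init_state = plant.initialize_posture(ref_angle(0.0))
        return self._simulate(plant, measured, init_state)


def calibrate_strength(
    measured: MomentTrace,
    plant: TrunkPlant,
    controller: ControllerParams | None = None,
    config: CalibrationConfig | None = None,
    coupling: SynergyCoupling | None = None,
) -> CalibrationResult:
    """Functional wrapper over :class:`StrengthIdentifier`."""
    cfg = config or CalibrationConfig()
    ident = StrengthIdentifier(
        plant=plant,
        controller=controller,
        delta=cfg.delta,
        max_iters=cfg.max_iters,
        with_synergy=cfg.with_synergy,
        with_iap=cfg.with_iap,
        coupling=coupling,
    ).fit(measured)
    return ident.result_


def personalize_fiber_length(
    active: TrialResult,
    misom: MomentTrace,
    plant: TrunkPlant,
    muscles: tuple[str, ...] = ("ES", "RA"),
    target: str = "l0",
) -> TrunkPlant:
    """Set the optimal fiber length of the named muscles to the fiber length
    at the per-cycle peak-moment instants (mean across cycles).

    Extension-segment maxima personalize the extensors, flexion-segment
    minima the flexors.  With ``target='optimum'`` the peak-length is
    instead placed at the force-length optimum 0.95 l0.
    """
    from dataclasses import replace

    t = misom.time
    lever = active.lever_angle_deg
    segs = segment_phases(t, lever)
    new_plant = copy.deepcopy(plant)
    for name in muscles:
        m = new_plant.muscle(name)
        phase = "Ext" if m.group == "extensor" else "Flx"
        pick = [s for s, p in segs if p == phase]
        if len(pick) < 2:
            raise ValueError(
                f"insufficient data: need >= 2 {phase} cycles to personalize {name}"
            )
        lengths = []
        for s in pick:
            idx = s.start + (
                int(np.argmax(misom.moment[s])) if phase == "Ext" else int(np.argmin(misom.moment[s]))
            )
            lengths.append(float(active.fiber_length[name][idx]))
        l_peak = float(np.mean(lengths))
        l0_new = l_peak if target == "l0" else l_peak / 0.95
        new_plant.muscles = [
            replace(mm, l0=l0_new) if mm.name == name else mm for mm in new_plant.muscles
        ]
    return new_plant
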