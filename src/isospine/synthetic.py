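"""Synthetic ground-truth subjects: isokinetic "measured" moment traces and
surrogate multi-channel EMG with planted two-synergy structure.

The generator stands in for recruited subjects: each seeded subject owns
true flexor/extensor strength scales (uniform in [0.6, 1.6] of the
generic plant), a planted 8-channel, 2-synergy spatial matrix with
agonist weights in [0.6, 1.0] and antagonist leakage in [0.1, 0.4]
(mimicking measured co-contraction), and noise levels.  The "measured"
trace is produced by a maximal-effort activation *script* — not the PD
controller used during identification, so the calibration loop never
trivially inverts itself — and the EMG is an amplitude-modulated
band-limited carrier whose envelope is the planted W.H(t).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .emg import EmgRecording
from .identify import simulate_trial
from .plant import IsokineticProtocol, TrunkPlant, default_plant
from .trace import MomentTrace

__all__ = [
    "EMG_CHANNELS",
    "CHANNEL_GROUPS",
    "SyntheticSubject",
    "make_subject",
    "make_measured_trace",
    "make_emg",
]

#: bilateral channel set: rectus abdominis, external oblique, erector
#: spinae and lower trapezius
EMG_CHANNELS = [
    "RA_left", "RA_right", "EO_left", "EO_right",
    "ES_left", "ES_right", "LT_left", "LT_right",
]

#: flexor/extensor grouping of the channels; the lower trapezius is
#: recorded but belongs to neither group
CHANNEL_GROUPS = {
    "RA_left": "flexor", "RA_right": "flexor",
    "EO_left": "flexor", "EO_right": "flexor",
    "ES_left": "extensor", "ES_right": "extensor",
    "LT_left": "other", "LT_right": "other",
}


@dataclass
class SyntheticSubject:
    seed: int
    f0_scale: dict[str, float]  # per group, dimensionless
    planted_W: np.ndarray  # channels x 2, column 0 flexor-dominated
    moment_noise_sd: float = 5.0  # N m
    emg_noise_sd: float = 0.05  # relative to envelope peak
    ramp_time: float = 0.25  # s, activation-script rise time

    @property
    def leakage_ratio_flexor(self) -> float:
        """Flexor co-contraction level during extension: mean flexor-channel
        weight in the extensor-dominated column over the mean flexor weight
        in the flexor-dominated column."""
        flx = [i for i, c in enumerate(EMG_CHANNELS) if CHANNEL_GROUPS[c] == "flexor"]
        return float(self.planted_W[flx, 1].mean() / self.planted_W[flx, 0].mean())

    @property
    def leakage_ratio_extensor(self) -> float:
        ext = [i for i, c in enumerate(EMG_CHANNELS) if CHANNEL_GROUPS[c] == "extensor"]
        return float(self.planted_W[ext, 0].mean() / self.planted_W[ext, 1].mean())


def make_subject(
    seed: int,
    moment_noise_sd: float = 5.0,
    emg_noise_sd: float = 0.05,
) -> SyntheticSubject:
    """Deterministic seeded subject with strength scales in [0.6, 1.6]."""
    rng = np.random.default_rng(seed)
    scales = {
        "extensor": float(rng.uniform(0.6, 1.6)),
        "flexor": float(rng.uniform(0.6, 1.6)),
    }
    W = np.zeros((len(EMG_CHANNELS), 2))
    for i, ch in enumerate(EMG_CHANNELS):
        grp = CHANNEL_GROUPS[ch]
        dom = rng.uniform(0.6, 1.0)
        leak = rng.uniform(0.1, 0.4)
        if grp == "flexor":
            W[i] = (dom, leak)
        elif grp == "extensor":
            W[i] = (leak, dom)
        else:  # lower trapezius co-activates with the extensors
            W[i] = (rng.uniform(0.1, 0.3), rng.uniform(0.4, 0.8))
    return SyntheticSubject(
        seed=seed, f0_scale=scales, planted_W=W,
        moment_noise_sd=moment_noise_sd, emg_noise_sd=emg_noise_sd,
    )


def _script_activation(t: np.ndarray, protocol: IsokineticProtocol, ramp: float):
    """Per-phase maximal-effort agonist profile in [0, 1]: linear rise over
    ``ramp`` seconds at each phase onset, hold, and symmetric release over
    the final ``ramp`` seconds (the subject lets go as the lever
    decelerates into the reversal, so the moment passes smoothly through
    zero as real dynamometer curves do).  Returns (a_ext(t), a_flx(t))."""
    a_ext = np.zeros_like(t)
    a_flx = np.zeros_like(t)
    for t0, t1, phase in protocol.phase_intervals():
        m = (t >= t0) & (t < t1)
        prof = np.clip(np.minimum((t[m] - t0) / ramp, (t1 - t[m]) / ramp), 0.0, 1.0)
        if phase == "Ext":
            a_ext[m] = prof
        else:
            a_flx[m] = prof
    return a_ext, a_flx


class _ScriptController:
    """Duck-typed stand-in for PDController: replays a precomputed
    activation schedule."""

    def __init__(self, times, act_by_name, dt):
        self.times = times
        self.act_by_name = act_by_name
        self.params = type("P", (), {"dt": dt, "tau_preview": 0.0})()

    def reset(self):
        pass

    def update(self, t, ref_angle, theta_sim, t_end, phase=None):
        k = min(int(round(t / self.params.dt)), len(self.times) - 1)
        return {n: float(a[k]) for n, a in self.act_by_name.items()}


def make_measured_trace(
    subject: SyntheticSubject,
    plant: TrunkPlant | None = None,
    protocol: IsokineticProtocol | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[MomentTrace, TrunkPlant]:
    """Forward-simulate the subject's ground truth into a "measured" trace.

    The subject's true F0 (group scale times the generic plant) drives a
    maximal-effort script: the agonist ramps to full activation each
    phase while the antagonist co-contracts at the planted leakage ratio.
    Gaussian moment noise is added and the curve is low-pass filtered
    with a fourth-order 6-Hz Butterworth filter, as an isokinetic
    dynamometer's output would be.  Returns the trace and the truth plant.
    """
    protocol = protocol or IsokineticProtocol()
    base = plant or default_plant()
    truth = _scaled_plant(base, subject)
    rng = rng or np.random.default_rng(subject.seed + 10_000)

    dt_c = 0.01
    t = np.arange(int(round(protocol.duration / dt_c)) + 1) * dt_c
    a_ext, a_flx = _script_activation(t, protocol, subject.ramp_time)
    r_flx = subject.leakage_ratio_flexor
    r_ext = subject.leakage_ratio_extensor
    floor = 0.02
    acts = {}
    for m in truth.muscles:
        if m.group == "extensor":
            acts[m.name] = np.clip(np.maximum(a_ext, r_ext * a_flx), floor, 1.0)
        else:
            acts[m.name] = np.clip(np.maximum(a_flx, r_flx * a_ext), floor, 1.0)

    ctrl = _ScriptController(t, acts, dt_c)
    init = truth.initialize_posture(math.radians(float(protocol.angle_deg(0.0))))
    active = simulate_trial(truth, protocol, ctrl, init_state=init)
    passive = simulate_trial(truth, protocol, None, passive=True, init_state=init)
    misom = active.trace.moment - passive.trace.moment
    if subject.moment_noise_sd > 0:
        misom = misom + rng.normal(0.0, subject.moment_noise_sd, size=misom.shape)
    sos = signal.butter(4, 6.0 / (0.5 / dt_c), btype="lowpass", output="sos")
    misom = signal.sosfiltfilt(sos, misom)
    trace = MomentTrace(t, protocol.angle_deg(t), misom, kind="measured")
    return trace, truth


def _scaled_plant(base: TrunkPlant, subject: SyntheticSubject) -> TrunkPlant:
    import copy

    truth = copy.deepcopy(base)
    truth.set_f0_scale("extensor", subject.f0_scale["extensor"])
    truth.set_f0_scale("flexor", subject.f0_scale["flexor"])
    return truth


def make_emg(
    subject: SyntheticSubject,
    protocol: IsokineticProtocol | None = None,
    fs: float = 2000.0,
    rng: np.random.Generator | None = None,
) -> EmgRecording:
    """Surrogate 8-channel EMG with planted synergy structure.

    The channel envelope is planted_W . H(t), where H holds one smooth
    phase-locked bump train per synergy (flexor activations during
    flexion phases, extensor during extension), plus relative Gaussian
    envelope noise.  The raw signal is the envelope amplitude-modulating
    a band-limited (10-250 Hz) zero-mean Gaussian carrier, in mV.
    """
    protocol = protocol or IsokineticProtocol()
    rng = rng or np.random.default_rng(subject.seed + 20_000)
    n = int(round(protocol.duration * fs)) + 1
    t = np.arange(n) / fs

    H = np.zeros((2, n))
    for t0, t1, phase in protocol.phase_intervals():
        m = (t >= t0) & (t <= t1)
        x = (t[m] - t0) / (t1 - t0)
        bump = np.sin(np.pi * np.clip(x, 0.0, 1.0)) ** 2
        H[1 if phase == "Ext" else 0, m] = np.maximum(
            H[1 if phase == "Ext" else 0, m], bump
        )

    env = subject.planted_W @ H  # channels x time, unitless
    if subject.emg_noise_sd > 0:
        env = env + rng.normal(0.0, subject.emg_noise_sd * env.max(), size=env.shape)
    env = np.maximum(env, 0.0)

    sos = signal.butter(3, [10.0 / (fs / 2), 250.0 / (fs / 2)], btype="bandpass", output="sos")
    carrier = signal.sosfilt(sos, rng.standard_normal(env.shape), axis=1)
    carrier /= carrier.std(axis=1, keepdims=True)
    raw = 0.5 * env * carrier  # mV scale
    channel_map = {i: ch for i, ch in enumerate(EMG_CHANNELS)}
    return EmgRecording(raw, fs, channel_map)
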