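"""Time/angle/moment series for isokinetic trials.

Angles are flexion-positive degrees; moments extension-positive N m.
A trace may hold a measured curve, a simulated active (M_act) or passive
(M_deact) constraint moment, or their difference, the simulated
isokinetic moment M_isom.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["MomentTrace", "segment_phases", "avg_first_extrema"]

KINDS = ("measured", "simulated_active", "simulated_passive", "isom")


@dataclass
class MomentTrace:
    time: np.ndarray
    angle_deg: np.ndarray
    moment: np.ndarray
    kind: str = "measured"

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.angle_deg = np.asarray(self.angle_deg, dtype=float)
        self.moment = np.asarray(self.moment, dtype=float)
        if self.kind not in KINDS:
            raise ValueError(f"unknown trace kind {self.kind!r}")
        if not (len(self.time) == len(self.angle_deg) == len(self.moment)):
            raise ValueError("time, angle and moment must have equal lengths")
        if len(self.time) < 2 or np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing with >= 2 samples")

    def __len__(self) -> int:
        return len(self.time)

    def resample_moment(self, time: np.ndarray) -> np.ndarray:
        return np.interp(time, self.time, self.moment)

    def resample_angle(self, time: np.ndarray) -> np.ndarray:
        return np.interp(time, self.time, self.angle_deg)


def segment_phases(time: np.ndarray, angle_deg: np.ndarray, min_samples: int = 3):
    """Split a trial at angular-velocity sign changes.

    Returns a list of (slice, phase) with phase 'Ext' where the angle
    decreases (movement toward extension) and 'Flx' where it increases.
    Segments shorter than ``min_samples`` are dropped.
    """
    v = np.gradient(angle_deg, time)
    sign = np.where(v < 0, -1, 1)
    out = []
    start = 0
    for i in range(1, len(sign)):
        if sign[i] != sign[start]:
            if i - start >= min_samples:
                out.append((slice(start, i), "Ext" if sign[start] < 0 else "Flx"))
            start = i
    if len(sign) - start >= min_samples:
        out.append((slice(start, len(sign)), "Ext" if sign[start] < 0 else "Flx"))
    return out


def avg_first_extrema(
    time: np.ndarray,
    angle_deg: np.ndarray,
    moment: np.ndarray,
    phase: str,
    n: int = 3,
) -> float:
    """Mean of the first ``n`` per-cycle moment extrema of one movement phase.

    Extension segments contribute their maxima, flexion segments their
    minima.  If fewer than ``n`` segments exist, the available ones are
    used (the caller is expected to warn).
    """
    segs = [s for s, p in segment_phases(time, angle_deg) if p == phase]
    if not segs:
        raise ValueError(f"no {phase} segments found in trace")
    pick = segs[:n]
    if phase == "Ext":
        vals = [float(np.max(moment[s])) for s in pick]
    else:
        vals = [float(np.min(moment[s])) for s in pick]
    return float(np.mean(vals))
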