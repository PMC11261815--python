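"""Surface-EMG conditioning: band-pass, rectification, envelope, MVC
normalization, and activation dynamics.

The processing chain mirrors standard isokinetic sEMG practice: a
sixth-order Butterworth band-pass (10-250 Hz) removes motion artefact and
high-frequency noise, full-wave rectification and a fourth-order 6-Hz
Butterworth low-pass produce the linear envelope, and each channel is
normalized by its maximal value over the trial set (MVC) to yield the
dimensionless neural stimulus u in [0, 1].  Filtering is zero-phase
(forward-backward) by default, which doubles the effective order but
introduces no lag; set ``zero_phase=False`` for single-pass behavior.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal
from sklearn.base import BaseEstimator, TransformerMixin

from .hill import ActivationParams, activation_step

__all__ = [
    "EmgRecording",
    "EnvelopeMatrix",
    "EmgEnvelope",
    "envelope",
    "normalize_mvc",
    "stimulus_to_activation",
]


@dataclass
class EmgRecording:
    """Raw multi-channel surface EMG.

    samples: (channels, time) array in mV; fs: sampling rate in Hz;
    channel_map: channel index -> muscle label (e.g. "RA_left").
    """

    samples: np.ndarray
    fs: float
    channel_map: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2 or self.samples.shape[0] < 2:
            raise ValueError("EMG recording needs a (channels, time) matrix with >= 2 channels")

    @property
    def labels(self) -> list[str]:
        return [self.channel_map.get(i, f"ch{i}") for i in range(self.samples.shape[0])]


@dataclass
class EnvelopeMatrix:
    """Non-negative envelope matrix (channels x time)."""

    values: np.ndarray
    fs_out: float
    labels: list[str] = field(default_factory=list)
    mvc_per_channel: np.ndarray | None = None
    dead_channels: list[int] = field(default_factory=list)

    @property
    def normalized(self) -> bool:
        return self.mvc_per_channel is not None


def _bandpass_sos(fs: float, lo: float, hi: float, order: int = 6):
    nyq = fs / 2.0
    if fs < 2.0 * hi + 100.0:
        raise ValueError(
            f"sampling rate {fs} Hz too low for a {lo}-{hi} Hz band-pass; need >= {2*hi+100:.0f} Hz"
        )
    # scipy's N is the per-edge order: N=3 yields a 6th-order band-pass
    return signal.butter(order // 2, [lo / nyq, hi / nyq], btype="bandpass", output="sos")


def envelope(
    raw: EmgRecording,
    band: tuple[float, float] = (10.0, 250.0),
    lowpass_hz: float = 6.0,
    zero_phase: bool = True,
) -> EnvelopeMatrix:
    """Band-pass, rectify, and low-pass the raw EMG into a linear envelope.

    Returns the un-normalized envelope (same units as the input), floored
    at zero; use :func:`normalize_mvc` to obtain the neural stimulus u.
    """
    sos_bp = _bandpass_sos(raw.fs, *band)
    sos_lp = signal.butter(4, lowpass_hz / (raw.fs / 2.0), btype="lowpass", output="sos")
    filt = signal.sosfiltfilt if zero_phase else signal.sosfilt
    x = filt(sos_bp, raw.samples, axis=1)
    x = np.abs(x)
    x = filt(sos_lp, x, axis=1)
    return EnvelopeMatrix(np.maximum(x, 0.0), raw.fs, labels=raw.labels)


def normalize_mvc(env: EnvelopeMatrix, mvc: np.ndarray | None = None) -> EnvelopeMatrix:
    """Divide each channel by its MVC (per-channel maximum over the trial set).

    All-zero channels cannot be normalized; they are flagged in
    ``dead_channels`` and left at zero (excluded from synergy input).
    Passing a precomputed ``mvc`` (e.g. the max over several trials)
    overrides the per-trial maximum.
    """
    values = np.asarray(env.values, dtype=float)
    mvc = values.max(axis=1) if mvc is None else np.asarray(mvc, dtype=float)
    dead = [i for i in range(values.shape[0]) if mvc[i] <= 0]
    safe = np.where(mvc > 0, mvc, 1.0)
    out = np.clip(values / safe[:, None], 0.0, 1.0)
    return EnvelopeMatrix(out, env.fs_out, labels=list(env.labels), mvc_per_channel=mvc, dead_channels=dead)


def stimulus_to_activation(
    u_series: np.ndarray, fs: float, params: ActivationParams | None = None
) -> np.ndarray:
    """Integrate the activation ODE along each channel of a stimulus series.

    ``u_series`` is (channels, time) or (time,) with entries in [0, 1];
    a(0) = u(0) per channel.
    """
    params = params if params is not None else ActivationParams()
    u = np.atleast_2d(np.asarray(u_series, dtype=float))
    if np.any((u < 0) | (u > 1)):
        raise ValueError("neural stimulus must lie in [0, 1]")
    dt = 1.0 / fs
    a = np.empty_like(u)
    a[:, 0] = u[:, 0]
    for ch in range(u.shape[0]):
        ai = u[ch, 0]
        for k in range(1, u.shape[1]):
            ai = activation_step(ai, u[ch, k], params, dt)
            a[ch, k] = ai
    out = a if np.asarray(u_series).ndim == 2 else a[0]
    return out


class EmgEnvelope(TransformerMixin, BaseEstimator):
    """sklearn-style transformer: raw EMG (time x channels) -> normalized envelope.

    ``fit`` learns the per-channel MVC from the training trials;
    ``transform`` filters, rectifies, low-passes and normalizes.  Rows are
    time samples and columns channels, matching the sklearn convention.
    """

    def __init__(
        self,
        fs: float = 2000.0,
        band: tuple[float, float] = (10.0, 250.0),
        lowpass_hz: float = 6.0,
        zero_phase: bool = True,
    ) -> None:
        self.fs = fs
        self.band = band
        self.lowpass_hz = lowpass_hz
        self.zero_phase = zero_phase

    def _envelope(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] < 2:
            raise ValueError("expected (n_samples, n_channels) with >= 2 channels")
        rec = EmgRecording(X.T, self.fs, {})
        return envelope(rec, self.band, self.lowpass_hz, self.zero_phase).values

    def fit(self, X, y=None):
        env = self._envelope(X)
        self.mvc_ = env.max(axis=1)
        self.n_features_in_ = env.shape[0]
        return self

    def transform(self, X) -> np.ndarray:
        env = self._envelope(X)
        em = normalize_mvc(EnvelopeMatrix(env, self.fs), mvc=getattr(self, "mvc_", None))
        return em.values.T
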