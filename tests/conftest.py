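import math

import numpy as np
import pytest
from hypothesis import settings

from isospine import IsokineticProtocol, MomentTrace, default_plant

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture
def plant():
    return default_plant()


@pytest.fixture
def protocol():
    return IsokineticProtocol()


@pytest.fixture
def short_protocol():
    """Two-cycle protocol for fast closed-loop tests."""
    return IsokineticProtocol(cycles=2)


def single_cycle_trace(peak_ext: float, peak_flx: float, cycles: int = 1) -> MomentTrace:
    """Idealized trial: triangle angle (+30 -> -30 -> +30 per cycle) with one
    smooth moment bump per phase, peaking at the given values."""
    dt = 0.01
    t = np.arange(int(round(4.0 * cycles / dt)) + 1) * dt
    tau = t % 4.0
    angle = np.where(tau < 2.0, 30.0 - 30.0 * tau, -30.0 + 30.0 * (tau - 2.0))
    bump = np.sin(np.pi * (tau % 2.0) / 2.0) ** 2
    moment = np.where(tau < 2.0, peak_ext * bump, peak_flx * bump)
    return MomentTrace(t, angle, moment, kind="measured")
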