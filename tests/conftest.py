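import numpy as np
import pytest

from respassist import (
    ControllerConfig,
    LungParams,
    SessionSpec,
    subject_from_table,
)
from respassist.loop import TRACE_COLUMNS, SessionTrace


@pytest.fixture
def lung_identified() -> LungParams:
    """The identified physiological lung parameters used throughout."""
    return LungParams(R=2.7, E=4.8)


@pytest.fixture
def default_cfg() -> ControllerConfig:
    return ControllerConfig()


@pytest.fixture
def s1_subject():
    return subject_from_table("S1")


@pytest.fixture
def s1_noiseless():
    return subject_from_table("S1").noiseless()


def make_trace(Q: np.ndarray, fs: float = 200.0, **overrides) -> SessionTrace:
    """Assemble a SessionTrace around a flow signal.

    V is the trapezoidal integral of Q; any unspecified channel is zero
    and the phase label column is left unlabelled (offline segmentation
    does not read it).
    """
    Q = np.asarray(Q, dtype=float)
    n = Q.size
    dt = 1.0 / fs
    v = np.empty(n)
    v[0] = 0.0
    np.cumsum((Q[1:] + Q[:-1]) * (dt / 2.0), out=v[1:])
    cols = {c: np.zeros(n) for c in TRACE_COLUMNS}
    cols["t"] = np.arange(n) * dt
    cols["Q"] = Q
    cols["V"] = v
    cols["phase_label"] = np.full(n, "unlabelled", dtype="<U11")
    cols.update(overrides)
    return SessionTrace(fs=fs, **cols)


def sine_flow(Q0: float, rate: float, duration: float, fs: float = 200.0) -> np.ndarray:
    t = np.arange(int(round(duration * fs))) / fs
    return Q0 * np.sin(2.0 * np.pi * rate / 60.0 * t)


@pytest.fixture
def sine_trace():
    """Pure sine flow at 0.5 L/s amplitude, 12 breaths/min, 60 s."""
    return make_trace(sine_flow(0.5, 12.0, 60.0))


@pytest.fixture
def short_spec_pair():
    """Matched natural/assisted specs (20 breaths/min, 30 s, shared seed)."""
    return (
        SessionSpec("natural", 20.0, 30.0, seed=11),
        SessionSpec("assisted", 20.0, 30.0, seed=11),
    )
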