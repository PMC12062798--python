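"""Sampled closed-loop session runner.

Couples the virtual subject (muscle-pressure waveform + R-E lung), the
dual-layer controller, the pneumatic plant and the force-pressure
transmission into one fixed-rate loop mirroring the crossover protocol:
baseline (natural breathing, robot absent) versus assisted sessions at
metronome rates of 12/20/30/40 breaths/min.

Timing: the physical simulation and sensor sampling run at fs (default
200 Hz); the controller updates at fs/2 (100 Hz) with zero-order hold;
sensor reads carry a one-sample (5 ms) communication latency; the
pneumatic actuator adds its own 200 ms dead time.

The lung is advanced with the trapezoidal discretisation, and flow is
read out from the pressure balance, so every trace satisfies the sampled
pressure identity R*Q + E*V = Pmus + Pexo and trapezoidal volume
conservation exactly (before sensor noise).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import lung as lung_mod
from .cohort import VirtualSubject
from .controller import (
    EXPIRATION,
    INSPIRATION,
    ControllerConfig,
    PhaseState,
    control_current,
    desired_force,
    desired_pressure_profile,
    estimate_phase,
    plan_force,
    supply_pressure_ref,
)
from .pneumatics import PneumaticParams, PneumaticState, step_dynamics

__all__ = [
    "SessionSpec",
    "SessionTrace",
    "TRACE_COLUMNS",
    "run_session",
    "run_crossover",
    "check_safety",
    "session_seed",
    "NATURAL",
    "ASSISTED",
]

NATURAL = "natural"
ASSISTED = "assisted"

TRACE_COLUMNS = [
    "t",
    "phase_label",
    "theta",
    "Q",
    "V",
    "Pmus",
    "Pexo",
    "Pexo_ref",
    "Fa",
    "Fint",
    "Fplan",
    "Psup",
    "Psup_ref",
    "I",
]

# Belt-engagement ramp scale: the pretension share of the applied force
# builds continuously as the chamber inflates (mu * min(1, Psup/ENGAGE_KPA)),
# vanishing with the chamber fully deflated. The affine force law holds
# once the chamber pressure exceeds this scale.
ENGAGE_KPA = 1.0

_SMOOTH_WINDOW = 5  # samples, causal moving average for flow / Fint / theta-derivatives


@dataclass(frozen=True)
class SessionSpec:
    """One session of the protocol."""

    mode: str
    rate: float
    duration: float = 180.0
    seed: int = 0
    fs: float = 200.0
    control_divisor: int = 2
    sensor_delay_samples: int = 1

    def __post_init__(self) -> None:
        if self.mode not in (NATURAL, ASSISTED):
            raise ValueError(f"mode must be '{NATURAL}' or '{ASSISTED}', got {self.mode!r}")
        if not self.duration > 0:
            raise ValueError("duration must be positive")
        if not self.fs > 0:
            raise ValueError("sampling rate must be positive")
        if self.control_divisor < 1 or self.sensor_delay_samples < 0:
            raise ValueError("invalid timing configuration")


@dataclass
class SessionTrace:
    """Uniformly sampled record of every loop signal.

    Arrays (equal length, sampled at fs): t (s), phase_label, theta, Q
    (L/s, measured flow, expiration positive), V (L, trapezoidal integral
    of Q), Pmus/Pexo/Pexo_ref (cmH2O), Fa/Fint/Fplan (N), Psup/Psup_ref
    (kPa), I (valve current).
    """

    fs: float
    t: np.ndarray
    phase_label: np.ndarray
    theta: np.ndarray
    Q: np.ndarray
    V: np.ndarray
    Pmus: np.ndarray
    Pexo: np.ndarray
    Pexo_ref: np.ndarray
    Fa: np.ndarray
    Fint: np.ndarray
    Fplan: np.ndarray
    Psup: np.ndarray
    Psup_ref: np.ndarray
    I: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = self.t.size
        for name in TRACE_COLUMNS:
            if getattr(self, name).shape != (n,):
                raise ValueError(f"trace column {name} misaligned")

    @property
    def n_samples(self) -> int:
        return self.t.size

    @property
    def dt(self) -> float:
        return 1.0 / self.fs

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({c: getattr(self, c) for c in TRACE_COLUMNS})

    def to_csv(self, path) -> None:
        """Write the trace; floats at 17 significant digits (round-trip exact)."""
        self.to_dataframe().to_csv(path, index=False, float_format="%.17g")

    @classmethod
    def from_csv(cls, path, fs: float | None = None) -> "SessionTrace":
        df = pd.read_csv(path)
        missing = [c for c in TRACE_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"trace file {path} missing columns {missing}")
        t = df["t"].to_numpy(dtype=float)
        if fs is None:
            if t.size < 2:
                raise ValueError("cannot infer sampling rate from a single sample")
            dts = np.diff(t)
            if np.ptp(dts) > 1e-9:
                raise ValueError("non-uniform sampling in trace file")
            fs = 1.0 / float(np.mean(dts))
        cols = {
            c: (
                df[c].to_numpy(dtype=object).astype(str)
                if c == "phase_label"
                else df[c].to_numpy(dtype=float)
            )
            for c in TRACE_COLUMNS
        }
        return cls(fs=float(fs), **cols)


class _SmoothedThetaDerivative:
    """Causal derivative of a signal with respect to the expiratory phase.

    Both the signal and theta are smoothed with a short moving average
    before first-order differencing, and the raw quotient is exponentially
    smoothed (dividing by per-tick phase increments of order 1e-2 would
    otherwise amplify sensor noise into the force plan); outside
    expiration (theta frozen or reset) the derivative is held at zero.
    """

    def __init__(self, window: int = _SMOOTH_WINDOW, ema: float = 0.3):
        self._win = window
        self._ema = ema
        self._xbuf: list[float] = []
        self._tbuf: list[float] = []
        self._prev: tuple[float, float] | None = None
        self._value = 0.0

    def reset(self) -> None:
        self._xbuf.clear()
        self._tbuf.clear()
        self._prev = None
        self._value = 0.0

    def update(self, x: float, theta: float) -> float:
        self._xbuf.append(x)
        self._tbuf.append(theta)
        if len(self._xbuf) > self._win:
            self._xbuf.pop(0)
            self._tbuf.pop(0)
        xs = sum(self._xbuf) / len(self._xbuf)
        ts = sum(self._tbuf) / len(self._tbuf)
        if self._prev is None:
            self._prev = (xs, ts)
            return 0.0
        x0, t0 = self._prev
        self._prev = (xs, ts)
        dtheta = ts - t0
        if dtheta <= 1e-9:
            self._value = 0.0
            return 0.0
        raw = (xs - x0) / dtheta
        self._value += self._ema * (raw - self._value)
        return self._value


def session_seed(root_seed: int, *key: int) -> int:
    """Deterministic session seed derived from a root seed and integer keys."""
    ss = np.random.SeedSequence([int(root_seed), *[int(k) for k in key]])
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def run_session(
    subject: VirtualSubject,
    cfg: ControllerConfig,
    spec: SessionSpec,
    pneu: PneumaticParams | None = None,
    *,
    exact_inverse: bool = False,
) -> SessionTrace:
    """Simulate one session and return its trace.

    Deterministic for a fixed spec seed. In natural mode the robot is
    absent (Pexo = Fa = 0 throughout); in assisted mode assistance is
    generated only during estimated expiration. Sensor-noise and
    breath-jitter streams are derived from the seed independently of the
    mode, so a matched pair of sessions shares its physiology.
    """
    pneu = pneu or PneumaticParams()
    if pneu.Pin > cfg.Psup_max:
        raise ValueError(
            f"source pressure {pneu.Pin} kPa exceeds the supply ceiling {cfg.Psup_max} kPa"
        )
    assisted = spec.mode == ASSISTED
    fs = spec.fs
    dt = 1.0 / fs
    n = int(round(spec.duration * fs))
    if n < 2:
        raise ValueError("session too short")

    breath = subject.breath.__class__(
        Q0=subject.breath.Q0, rate=spec.rate, insp_fraction=subject.breath.insp_fraction
    )
    lung = subject.lung
    tm = subject.tm
    period = breath.period
    omega = 2.0 * math.pi / period
    profile = lung_mod.muscle_pressure_profile(breath.Q0, lung)
    a_mus, phi = profile.A_mus, profile.phi

    # --- seeded streams (mode-independent derivation) -------------------
    ss = np.random.SeedSequence([int(spec.seed)])
    jitter_ss, flow_ss, fint_ss = ss.spawn(3)
    n_breaths = int(math.ceil(spec.duration / period)) + 2
    jitter = 1.0 + subject.pmus_jitter_cv * np.random.default_rng(jitter_ss).standard_normal(
        n_breaths
    )
    np.clip(jitter, 0.1, None, out=jitter)
    flow_noise = subject.flow_noise_sd * np.random.default_rng(flow_ss).standard_normal(n)
    fint_noise = subject.fint_noise_sd * np.random.default_rng(fint_ss).standard_normal(n)

    t = np.arange(n) * dt
    b_idx = np.minimum((t / period).astype(int), n_breaths - 1)
    pmus = jitter[b_idx] * a_mus * np.sin(omega * t + phi)

    # --- preallocated trace columns -------------------------------------
    theta_arr = np.zeros(n)
    phase_arr = np.empty(n, dtype="<U11")
    q_arr = np.empty(n)
    pexo_arr = np.zeros(n)
    pexo_ref_arr = np.zeros(n)
    fa_arr = np.zeros(n)
    fint_arr = np.zeros(n)
    fplan_arr = np.zeros(n)
    psup_arr = np.zeros(n)
    psup_ref_arr = np.zeros(n)
    i_arr = np.zeros(n)

    # --- loop state ------------------------------------------------------
    a1, b_tz = lung_mod.trapezoid_coefficients(lung, dt)
    half_b = b_tz / 2.0
    R, E = lung.R, lung.E
    delta_c = tm.delta_cmh2o_per_n
    alpha_t, mu, fmax = tm.alpha_t, tm.mu, cfg.Fmax
    k1, cv, pin = pneu.k1, pneu.cv_effective, pneu.Pin
    hysteresis = 0.02 * breath.Q0
    min_phase = int(round(0.2 * (period / 2.0) * fs))
    mod_depth = subject.fint_modulation

    phase = PhaseState()
    # The valve->chamber path carries only the filling lag; the measured
    # ~200 ms actuation lag sits in the elasticity-adjustment mechanics
    # between chamber pressure and delivered belt force. It is modelled
    # as a first-order (viscoelastic) lag: soft-actuator/tissue mechanics
    # respond diffusively, and a transport dead time there would make the
    # interaction-force compliance loop a relay oscillator.
    pstate = PneumaticState(pneu, dt, delay=0.0)
    force_lag_decay = math.exp(-dt / pneu.delay) if pneu.delay > 0 else 0.0
    psup_eff = 0.0
    flow_buf: list[float] = []
    fint_deriv = _SmoothedThetaDerivative()
    ref_deriv = _SmoothedThetaDerivative()
    meas_deriv = _SmoothedThetaDerivative()

    v = 0.0
    pexo = 0.0
    psup = 0.0
    fa = 0.0
    pexo_ref = 0.0
    fa_ref = 0.0
    fplan = 0.0
    psup_ref = 0.0
    current = 0.0
    q_meas_hist = [0.0] * spec.sensor_delay_samples
    cdiv = spec.control_divisor
    two_pi = 2.0 * math.pi
    n_saturated = 0

    for k in range(n):
        pmus_k = pmus[k]
        q_true = (pmus_k + pexo - E * v) / R
        q_meas = q_true + flow_noise[k]

        # interaction force measured at the belt
        fint = fa * (1.0 + mod_depth * math.sin(two_pi * phase.theta)) + fint_noise[k]
        if fint < 0.0:
            fint = 0.0

        # record state at sample k
        theta_arr[k] = phase.theta
        phase_arr[k] = phase.phase_label
        q_arr[k] = q_meas
        pexo_arr[k] = pexo
        pexo_ref_arr[k] = pexo_ref
        fa_arr[k] = fa
        fint_arr[k] = fint
        fplan_arr[k] = fplan
        psup_arr[k] = psup
        psup_ref_arr[k] = psup_ref
        i_arr[k] = current

        # sensor path: delayed, smoothed flow feeds the phase estimator
        q_meas_hist.append(q_meas)
        q_sensor = q_meas_hist.pop(0)
        flow_buf.append(q_sensor)
        if len(flow_buf) > _SMOOTH_WINDOW:
            flow_buf.pop(0)
        q_smooth = sum(flow_buf) / len(flow_buf)
        estimate_phase(q_smooth, phase, dt, hysteresis, min_phase_samples=min_phase)

        if assisted and (phase.phase_label != EXPIRATION or phase.warm_up):
            # assistance is expiration-only: cut the held references at the
            # sensor rate, not just at controller ticks
            pexo_ref = 0.0
            fa_ref = 0.0
            fplan = 0.0
            psup_ref = 0.0

        if assisted and k % cdiv == 0:
            in_expiration = phase.phase_label == EXPIRATION and not phase.warm_up
            if in_expiration:
                theta_c = phase.theta
                pexo_ref = desired_pressure_profile(theta_c, profile, cfg)
                fa_ref = desired_force(pexo_ref, tm, cfg)
                dfint = fint_deriv.update(fint, theta_c)
                # compliance modulates a commanded force; with no reference
                # there is nothing to plan (noise must not inflate the belt)
                fplan = plan_force(fa_ref, fint, dfint, cfg) if fa_ref > 0.0 else 0.0
                psup_ref = supply_pressure_ref(fplan, tm, cfg, exact_inverse=exact_inverse)
            else:
                pexo_ref = 0.0
                fa_ref = 0.0
                fplan = 0.0
                psup_ref = 0.0
                fint_deriv.reset()
            dref = ref_deriv.update(psup_ref, phase.theta)
            dmeas = meas_deriv.update(psup, phase.theta)
            current, sat = control_current(
                psup_ref, psup, dref, dmeas, cfg, k1, cv, pin
            )
            if sat:
                n_saturated += 1

        if k == n - 1:
            break

        if assisted:
            psup = step_dynamics(pneu, pstate, current, dt)
            psup_eff = psup + (psup_eff - psup) * force_lag_decay
            engage = psup_eff / ENGAGE_KPA
            if engage > 1.0:
                engage = 1.0
            fa = alpha_t * psup_eff + mu * engage
            if fa > fmax:
                fa = fmax
            pexo = delta_c * fa

        # trapezoidal lung step from sample k to k+1
        v = a1 * v + half_b * ((pmus_k + pexo_arr[k]) + (pmus[k + 1] + pexo))

    # volume bookkeeping: trapezoidal integral of the recorded flow
    v_arr = np.empty(n)
    v_arr[0] = 0.0
    np.cumsum((q_arr[1:] + q_arr[:-1]) * (dt / 2.0), out=v_arr[1:])

    return SessionTrace(
        fs=fs,
        t=t,
        phase_label=phase_arr,
        theta=theta_arr,
        Q=q_arr,
        V=v_arr,
        Pmus=pmus,
        Pexo=pexo_arr,
        Pexo_ref=pexo_ref_arr,
        Fa=fa_arr,
        Fint=fint_arr,
        Fplan=fplan_arr,
        Psup=psup_arr,
        Psup_ref=psup_ref_arr,
        I=i_arr,
        meta={
            "mode": spec.mode,
            "rate": spec.rate,
            "seed": spec.seed,
            "subject": subject.id,
            "n_saturated": n_saturated,
        },
    )


def check_safety(trace: SessionTrace, cfg: ControllerConfig) -> dict[str, float]:
    """Safety-envelope extrema of a session.

    Returns the maxima of total airway pressure (cmH2O), supply pressure
    and its reference (kPa), and applied force (N). ``violated`` is the
    count of bounds exceeded.
    """
    max_airway = float(np.max(trace.Pmus + trace.Pexo))
    max_psup = float(max(np.max(trace.Psup), np.max(trace.Psup_ref)))
    max_fa = float(np.max(trace.Fa))
    violated = sum(
        [
            max_airway > cfg.Pairway_max,
            max_psup > cfg.Psup_max,
            max_fa > cfg.Fmax,
        ]
    )
    return {
        "max_airway_cmh2o": max_airway,
        "max_psup_kpa": max_psup,
        "max_fa_n": max_fa,
        "violated": violated,
    }


def run_crossover(
    subject: VirtualSubject,
    cfg: ControllerConfig,
    rates=(12.0, 20.0, 30.0, 40.0),
    reps: int = 3,
    seed: int = 0,
    *,
    duration: float = 180.0,
    pneu: PneumaticParams | None = None,
    subject_index: int = 0,
) -> dict[tuple[float, int], tuple[SessionTrace, SessionTrace]]:
    """Paired baseline/assisted sessions at each metronome rate.

    Each (rate, rep) cell runs a natural and an assisted session from the
    same derived seed, so the pair shares its breath-jitter and
    sensor-noise streams (the subject acts as its own control). Returns
    ``{(rate, rep): (baseline_trace, assisted_trace)}``.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    out: dict[tuple[float, int], tuple[SessionTrace, SessionTrace]] = {}
    for rate in rates:
        for rep in range(reps):
            s = session_seed(seed, subject_index, int(round(rate * 1000)), rep)
            base = run_session(
                subject, cfg, SessionSpec(NATURAL, rate, duration, seed=s), pneu
            )
            asst = run_session(
                subject, cfg, SessionSpec(ASSISTED, rate, duration, seed=s), pneu
            )
            out[(rate, rep)] = (base, asst)
    return out
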