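"""Dual-layer assistive controller.

High level: from the estimated expiratory phase theta, generate the
reference assistive lung pressure ``Pexo_ref = assist_gain * A *
sin(pi*theta + phi)`` (never negative, and clipped so that the predicted
total airway pressure Pmus + Pexo_ref stays below the 30 cmH2O safety
ceiling), convert it to a reference assistive force through delta.

Low level: plan the force from interaction-force feedback,
``Fplan = Fa_ref - B*dFint/dtheta - K*Fint`` (damping + compliance), map
it to a supply-pressure reference through the force-pressure line, and
track that reference with a PD law wrapped in a square-root feedforward
that linearises the valve's flow-pressure characteristic:

    I = k1*Cv*sqrt(Pin - kP*e - kD*edot),  e = Psup_ref - Psup.

The closed error dynamics are asymptotically stable for kP > 1, kD > 0.

Phase estimation: breathing is first segmented into inspiration and
expiration by hysteresis on the (smoothed) flow signal; within an
expiration, theta is the expired volume so far divided by the total
expired volume predicted from the previous breath.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .lung import MusclePressureProfile
from .transmission import TransmissionModel

__all__ = [
    "ControllerConfig",
    "PhaseState",
    "StabilityReport",
    "estimate_phase",
    "desired_pressure_profile",
    "desired_force",
    "plan_force",
    "supply_pressure_ref",
    "control_current",
    "check_stability",
    "INSPIRATION",
    "EXPIRATION",
]

INSPIRATION = "inspiration"
EXPIRATION = "expiration"


@dataclass(frozen=True)
class ControllerConfig:
    """Gains and safety ceilings of the dual-layer controller.

    assist_gain: dimensionless fraction of the natural muscle-pressure
    amplitude delivered as assistance, in [0, 1].
    B, K: force-planning damping and stiffness gains (dimensionless, act on
    the interaction force and its phase derivative).
    kP, kD: pressure-tracking PD gains; stability requires kP > 1, kD > 0.
    Fmax / Psup_max / Pairway_max: hard safety ceilings (N, kPa, cmH2O).
    """

    assist_gain: float = 1.0
    B: float = 0.5
    K: float = 0.5
    kP: float = 2.6
    kD: float = 0.5
    Fmax: float = 400.0
    Psup_max: float = 20.0
    Pairway_max: float = 30.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.assist_gain <= 1.0:
            raise ValueError(f"assist_gain must be in [0, 1], got {self.assist_gain}")
        if not 0.1 <= self.B <= 10.0:
            raise ValueError(f"planning gain B must be in [0.1, 10.0], got {self.B}")
        if not 0.1 <= self.K <= 5.0:
            raise ValueError(f"planning gain K must be in [0.1, 5.0], got {self.K}")
        if not 1.0 < self.kP <= 10.0:
            raise ValueError(
                f"tracking gain kP must be in (1, 10] (kP > 1 for stability), got {self.kP}"
            )
        if not 0.0 < self.kD <= 1.0:
            raise ValueError(f"tracking gain kD must be in (0, 1], got {self.kD}")
        if not 0.0 < self.Fmax <= 400.0:
            raise ValueError(f"Fmax must be in (0, 400] N, got {self.Fmax}")
        if not 0.0 < self.Psup_max <= 20.0:
            raise ValueError(f"Psup_max must be in (0, 20] kPa, got {self.Psup_max}")
        if not self.Pairway_max > 0:
            raise ValueError(f"Pairway_max must be positive, got {self.Pairway_max}")


@dataclass
class PhaseState:
    """State of the online expiratory-phase estimator."""

    phase_label: str = INSPIRATION
    theta: float = 0.0
    vex_cum: float = 0.0
    vex_pred: float | None = None
    warm_up: bool = True
    samples_in_phase: int = 0
    pred_weight: float = 1.0  # EW update weight; 1.0 = pure previous breath

    def copy(self) -> "PhaseState":
        return replace(self)


def estimate_phase(
    flow_sample: float,
    state: PhaseState,
    dt: float,
    hysteresis: float,
    *,
    min_phase_samples: int = 0,
) -> PhaseState:
    """Advance the phase estimator by one flow sample (in place).

    Expiratory flow is positive. The binary label flips expiration ->
    inspiration when flow drops below -hysteresis and back when it exceeds
    +hysteresis; ``min_phase_samples`` debounces flips near the zero
    crossings. Within an expiration the continuous phase is
    ``theta = min(1, vex_cum / vex_pred)`` with vex_pred predicted from the
    previous completed expiration; during the first breath (no prediction
    yet) theta is pinned to 0 with ``warm_up=True``.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    state.samples_in_phase += 1
    can_flip = state.samples_in_phase >= min_phase_samples
    if state.phase_label == EXPIRATION:
        if can_flip and flow_sample < -hysteresis:
            # Expiration completed: update the prediction for the next one.
            if state.vex_cum > 0.0:
                if state.vex_pred is None:
                    state.vex_pred = state.vex_cum
                else:
                    w = state.pred_weight
                    state.vex_pred = w * state.vex_cum + (1.0 - w) * state.vex_pred
                state.warm_up = False
            state.phase_label = INSPIRATION
            state.samples_in_phase = 0
            state.theta = 0.0
            state.vex_cum = 0.0
        else:
            if flow_sample > 0.0:
                state.vex_cum += flow_sample * dt
            if state.vex_pred is None:
                state.theta = 0.0
            else:
                state.theta = min(1.0, state.vex_cum / state.vex_pred)
    else:
        if can_flip and flow_sample > hysteresis:
            state.phase_label = EXPIRATION
            state.samples_in_phase = 0
            state.vex_cum = 0.0
            state.theta = 0.0
    return state


def desired_pressure_profile(
    theta: float, profile: MusclePressureProfile, cfg: ControllerConfig
) -> float:
    """Reference assistive lung pressure at phase theta, cmH2O.

    ``assist_gain * A * sin(pi*theta + phi)``, floored at zero (the robot
    cannot suck) and clipped so that the model-predicted total airway
    pressure ``Pmus(theta) + Pexo_ref(theta)`` never exceeds Pairway_max.
    """
    if not 0.0 <= theta <= 1.0:
        raise ValueError(f"theta must be in [0, 1], got {theta}")
    pmus_pred = profile.A_mus * math.sin(math.pi * theta + profile.phi)
    p = cfg.assist_gain * pmus_pred
    if p < 0.0:
        return 0.0
    headroom = cfg.Pairway_max - pmus_pred
    if headroom <= 0.0:
        return 0.0
    return min(p, headroom)


def desired_force(P_exo_ref: float, tm: TransmissionModel, cfg: ControllerConfig) -> float:
    """Reference assistive force Fa_ref = Pexo_ref / delta, clamped to [0, Fmax]."""
    delta = tm.delta_cmh2o_per_n
    if delta <= 0:
        raise ValueError("delta must be positive")
    f = P_exo_ref / delta
    return min(max(f, 0.0), cfg.Fmax)


def plan_force(
    F_a_ref: float, F_int: float, dFint_dtheta: float, cfg: ControllerConfig
) -> float:
    """Interaction-force-compliant planned force, clamped to [0, Fmax].

    ``Fplan = Fa_ref - B*dFint/dtheta - K*Fint``: the damping term
    suppresses fast force transients, the stiffness term keeps the
    interface compliant. With zero feedback the reference passes through.
    """
    f = F_a_ref - cfg.B * dFint_dtheta - cfg.K * F_int
    return min(max(f, 0.0), cfg.Fmax)


def supply_pressure_ref(
    F_plan: float,
    tm: TransmissionModel,
    cfg: ControllerConfig,
    *,
    exact_inverse: bool = False,
) -> float:
    """Supply-pressure reference from the planned force, clamped to [0, Psup_max].

    Default mode divides by the force gain only (``F_plan / alpha_t``);
    ``exact_inverse`` inverts the full affine characteristic
    (``(F_plan - mu) / alpha_t``, floored at 0).
    """
    if exact_inverse:
        p = (F_plan - tm.mu) / tm.alpha_t
    else:
        p = F_plan / tm.alpha_t
    return min(max(p, 0.0), cfg.Psup_max)


def control_current(
    P_sup_ref: float,
    P_sup: float,
    dref_dtheta: float,
    dmeas_dtheta: float,
    cfg: ControllerConfig,
    k1: float,
    Cv: float,
    Pin: float,
) -> tuple[float, bool]:
    """PD + square-root feedforward valve current.

    ``I = k1*Cv*sqrt(Pin - kP*e - kD*edot)`` with ``e = Psup_ref - Psup``
    and ``edot`` the phase derivative of the error. The square root
    compensates the quadratic valve pressure drop. A negative radicand is
    floored at zero and flagged (saturated), never raised.

    Returns
    -------
    (I, saturated)
    """
    e = P_sup_ref - P_sup
    edot = dref_dtheta - dmeas_dtheta
    radicand = Pin - cfg.kP * e - cfg.kD * edot
    if radicand < 0.0:
        return 0.0, True
    return k1 * Cv * math.sqrt(radicand), False


@dataclass(frozen=True)
class StabilityReport:
    stable: bool
    margin: float
    lyapunov_nonincreasing: bool | None = None
    max_lyapunov_increase: float = 0.0


def _lyapunov_trajectory(kP: float, kD: float, x0=(1.0, 1.0), dt=1e-3, n=5000):
    """Lyapunov function V = x1^2/2 + x2^2/2 along the tracking-error dynamics.

    The stability argument yields Vdot = (1-kP)*x1^2 - kD*x2^2, i.e. the
    error coordinate decays at rate kP-1 and its derivative coordinate at
    rate kD. The trajectory is integrated with RK4.
    """
    x1, x2 = x0
    vs = np.empty(n + 1)
    vs[0] = 0.5 * (x1 * x1 + x2 * x2)

    a, b = -(kP - 1.0), -kD

    def _step(x, rate):
        k1 = rate * x
        k2 = rate * (x + 0.5 * dt * k1)
        k3 = rate * (x + 0.5 * dt * k2)
        k4 = rate * (x + dt * k3)
        return x + dt / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)

    for i in range(n):
        x1 = _step(x1, a)
        x2 = _step(x2, b)
        vs[i + 1] = 0.5 * (x1 * x1 + x2 * x2)
    return vs


def check_stability(
    cfg: ControllerConfig | None = None,
    *,
    kP: float | None = None,
    kD: float | None = None,
    numeric: bool = True,
    x0=(1.0, 1.0),
) -> StabilityReport:
    """Analytic (kP > 1 and kD > 0) plus numerical Lyapunov stability check.

    Gains are taken from ``cfg`` or passed explicitly (the explicit path
    admits values a ControllerConfig would refuse to hold, so candidate
    gains can be screened before configuration). The numerical part
    simulates the tracking-error dynamics and verifies that
    ``V = x1^2/2 + x2^2/2`` never increases by more than 1e-9 per step.
    """
    if cfg is not None:
        kP, kD = cfg.kP, cfg.kD
    if kP is None or kD is None:
        raise ValueError("provide either a ControllerConfig or both kP and kD")
    stable = kP > 1.0 and kD > 0.0
    margin = min(kP - 1.0, kD)
    if not (stable and numeric):
        return StabilityReport(stable=stable, margin=margin)
    vs = _lyapunov_trajectory(kP, kD, x0=x0)
    increases = np.diff(vs)
    max_inc = float(increases.max(initial=0.0))
    return StabilityReport(
        stable=stable,
        margin=margin,
        lyapunov_nonincreasing=bool(max_inc <= 1e-9),
        max_lyapunov_increase=max_inc,
    )
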