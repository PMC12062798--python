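"""Valve and chamber pneumatics.

Statics: supply flow through the proportional valve follows the orifice
(Bernoulli) law ``Qsup = Cf * A * sqrt(2*dP/rho)`` and is proportional to
the control current, ``Qsup = k1 * I``; combining the two gives the static
chamber pressure ``Psup = Pin - (I/(k1*Cf))**2`` (lumped coefficients, all
unit reconciliation confined to parameter construction).

Dynamics: the chamber is modelled as a first-order lag (filling time
constant tau_fill) behind a transport dead time; the dead time realises
the measured ~200 ms actuation lag of the soft actuator, the lag the
finite fill rate. The model relaxes toward the static characteristic, so
its equilibria coincide with it exactly.
"""

from __future__ import annotations

import math
from collections import deque
from dataclasses import dataclass

__all__ = [
    "PneumaticParams",
    "PneumaticState",
    "orifice_flow",
    "valve_flow",
    "static_pressure",
    "step_dynamics",
]


@dataclass(frozen=True)
class PneumaticParams:
    """Valve/chamber constants.

    Pin: source pressure, kPa (constant upstream supply).
    k1: current-to-flow coefficient, L/min per unit current.
    Cf: valve flow coefficient (dimensionless); Cv of the control law
        aliases to Cf unless set separately.
    A_orifice: orifice area, m^2.
    rho: gas density, kg/m^3.
    tau_fill: chamber filling time constant, s.
    delay: actuation dead time, s (measured lag of the soft actuator).
    """

    Pin: float = 16.0
    k1: float = 1.0
    Cf: float = 1.0
    Cv: float | None = None
    A_orifice: float = 1e-5
    rho: float = 1.2
    tau_fill: float = 0.030
    delay: float = 0.200

    def __post_init__(self) -> None:
        for name in ("Pin", "k1", "Cf", "A_orifice", "rho", "tau_fill"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.delay < 0:
            raise ValueError("delay must be >= 0")
        if self.Cv is not None and not self.Cv > 0:
            raise ValueError("Cv must be strictly positive when given")

    @property
    def cv_effective(self) -> float:
        return self.Cf if self.Cv is None else self.Cv


def orifice_flow(p: PneumaticParams, dP: float) -> float:
    """Orifice flow ``Q = Cf * A * sqrt(2*dP/rho)`` at pressure drop dP.

    Evaluated exactly as written: the caller supplies consistent units
    (dP in Pa with rho in kg/m^3 and A in m^2 yields Q in m^3/s).
    Reverse flow is not modelled.
    """
    if dP < 0:
        raise ValueError(f"pressure drop must be >= 0, got {dP}")
    return p.Cf * p.A_orifice * math.sqrt(2.0 * dP / p.rho)


def valve_flow(p: PneumaticParams, I: float) -> float:
    """Proportional-valve flow k1 * I (L/min)."""
    if I < 0:
        raise ValueError(f"control current must be >= 0, got {I}")
    return p.k1 * I


def static_pressure(p: PneumaticParams, I: float) -> float:
    """Static chamber pressure ``Pin - (I/(k1*Cf))**2`` (kPa), floored at 0."""
    if I < 0:
        raise ValueError(f"control current must be >= 0, got {I}")
    drop = (I / (p.k1 * p.Cf)) ** 2
    return max(p.Pin - drop, 0.0)


class PneumaticState:
    """Chamber pressure plus the dead-time queue of pending current commands."""

    def __init__(
        self,
        p: PneumaticParams,
        dt: float,
        Psup0: float = 0.0,
        delay: float | None = None,
    ):
        if dt <= 0:
            raise ValueError("dt must be positive")
        n_delay = int(round((p.delay if delay is None else delay) / dt))
        self.Psup = min(max(Psup0, 0.0), p.Pin)
        # Queue holds the currents issued during the last `delay` seconds;
        # a freshly issued command only reaches the chamber after that.
        # The pre-history is the holding current of the initial pressure,
        # so the output is unchanged until the first command propagates.
        i_hold = p.k1 * p.Cf * math.sqrt(max(p.Pin - self.Psup, 0.0))
        self._queue: deque[float] = deque([i_hold] * n_delay, maxlen=max(n_delay, 1))
        self._has_delay = n_delay > 0

    def delayed_current(self, I: float) -> float:
        if not self._has_delay:
            return I
        out = self._queue[0]
        self._queue.append(I)
        return out


def step_dynamics(p: PneumaticParams, state: PneumaticState, I: float, dt: float) -> float:
    """Advance chamber pressure by one step under current command I.

    Exact first-order update toward the static characteristic of the
    delayed current: ``Psup <- target + (Psup - target)*exp(-dt/tau)``,
    bounded in [0, Pin]. Returns (and stores) the new Psup.
    """
    i_eff = state.delayed_current(I)
    target = static_pressure(p, i_eff)
    psup = target + (state.Psup - target) * math.exp(-dt / p.tau_fill)
    psup = min(max(psup, 0.0), p.Pin)
    state.Psup = psup
    return psup
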