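"""Actuator-to-lung mechanical transmission.

Two linear maps connect the pneumatic actuator to the lungs:

1. supply pressure to assistive force, ``Fa = alpha_t * Psup + mu`` over
   the rated 0-20 kPa range (per-subject calibration, static fit);
2. assistive force to effective extra lung pressure, ``Pexo = delta * Fa``,
   where delta lumps the thoraco-abdominal cascade: force over the contact
   area raises abdominal pressure, the diaphragm transmits a volume change
   into the thorax, and thoracic elasticity converts it back to pressure
   with tissue efficiency eta, giving ``delta = kth*Cab*eta / (A*V0)``.

delta carries an explicit unit tag (cmH2O/N or kPa/N) because airway
pressures are accounted in cmH2O while the actuator side works in kPa.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy import stats

from .units import CMH2O_PER_KPA

__all__ = [
    "TransmissionModel",
    "CascadeConstants",
    "CalibrationResult",
    "PSUP_RATED_MAX_KPA",
    "force_from_pressure",
    "compose_delta",
    "cascade_pexo",
    "pexo_from_force",
    "calibrate_transmission",
]

PSUP_RATED_MAX_KPA = 20.0

DeltaUnit = Literal["cmH2O/N", "kPa/N"]


@dataclass(frozen=True)
class TransmissionModel:
    """Per-subject actuator-to-lung mapping.

    alpha_t: force gain, N/kPa (named to avoid clashing with the
    dimensionless assist gain of the high-level controller).
    mu: offset force at zero gauge supply pressure, N (belt pretension).
    delta: force-to-lung-pressure coefficient in the tagged unit.
    """

    alpha_t: float
    mu: float
    delta: float = 0.05
    delta_unit: DeltaUnit = "cmH2O/N"

    def __post_init__(self) -> None:
        if not self.alpha_t > 0:
            raise ValueError(f"force gain alpha_t must be > 0, got {self.alpha_t}")
        if self.mu < 0:
            raise ValueError(f"force offset mu must be >= 0, got {self.mu}")
        if not self.delta > 0:
            raise ValueError(f"transmission coefficient delta must be > 0, got {self.delta}")
        if self.delta_unit not in ("cmH2O/N", "kPa/N"):
            raise ValueError(f"unknown delta unit {self.delta_unit!r}")

    @property
    def delta_cmh2o_per_n(self) -> float:
        """delta expressed in cmH2O/N regardless of the stored tag."""
        if self.delta_unit == "cmH2O/N":
            return self.delta
        return self.delta * CMH2O_PER_KPA


@dataclass(frozen=True)
class CascadeConstants:
    """Constants of the thoraco-abdominal transmission cascade.

    A_contact: equivalent pressure-transmission contact area (m^2 scale,
    used in consistent units); Cab: diaphragmatic compliance; kth: thoracic
    elastic coefficient; V0: initial thoracic volume; eta: tissue
    transmission efficiency in (0, 1].
    """

    A_contact: float
    Cab: float
    kth: float
    V0: float
    eta: float

    def __post_init__(self) -> None:
        for name in ("A_contact", "Cab", "kth", "V0", "eta"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.eta > 1.0:
            raise ValueError(f"transmission efficiency eta must be <= 1, got {self.eta}")


@dataclass(frozen=True)
class CalibrationResult:
    """OLS fit of the force-pressure characteristic with goodness of fit.

    ``alpha_t`` and ``mu`` are the fitted slope/intercept; ``model`` is the
    corresponding TransmissionModel when the slope is physically admissible
    (strictly positive), else None (flagged degenerate).
    """

    alpha_t: float
    mu: float
    model: TransmissionModel | None
    r_squared: float
    pearson_r: float
    n: int
    degenerate: bool = False
    stderr_slope: float = field(default=float("nan"))
    stderr_intercept: float = field(default=float("nan"))

    def __post_init__(self) -> None:
        if not self.degenerate:
            if not 0.0 <= self.r_squared <= 1.0 + 1e-12:
                raise ValueError("R^2 out of [0, 1]")
            if not -1.0 - 1e-12 <= self.pearson_r <= 1.0 + 1e-12:
                raise ValueError("Pearson r out of [-1, 1]")

    def summary(self) -> str:
        lines = [
            "Force-pressure calibration (Fa = alpha_t * Psup + mu)",
            f"  n pairs        : {self.n}",
            f"  alpha_t [N/kPa]: {self.alpha_t:.4f} (SE {self.stderr_slope:.4f})",
            f"  mu      [N]    : {self.mu:.4f} (SE {self.stderr_intercept:.4f})",
            f"  R^2            : {self.r_squared:.4f}",
            f"  Pearson r      : {self.pearson_r:.4f}",
        ]
        if self.degenerate:
            lines.append("  WARNING: degenerate fit (no usable force-pressure slope)")
        return "\n".join(lines)


def force_from_pressure(tm: TransmissionModel, Psup: float) -> float:
    """Assistive force (N) at supply pressure Psup (kPa), rated 0-20 kPa."""
    if not 0.0 <= Psup <= PSUP_RATED_MAX_KPA:
        raise ValueError(
            f"supply pressure {Psup} kPa outside rated range "
            f"[0, {PSUP_RATED_MAX_KPA}] (clamp before calling)"
        )
    return tm.alpha_t * Psup + tm.mu


def compose_delta(c: CascadeConstants) -> float:
    """Lumped transmission coefficient delta = kth*Cab*eta / (A_contact*V0).

    Stored positive: the compressive sign of the thoracic-pressure step is
    absorbed into the expiration-positive convention.
    """
    denom = c.A_contact * c.V0
    if denom == 0:
        raise ZeroDivisionError("A_contact * V0 must be nonzero")
    return c.kth * c.Cab * c.eta / denom


def cascade_pexo(c: CascadeConstants, Fa: float) -> float:
    """Chain the cascade stage by stage (force -> Pab -> dVab -> dPth -> Pexo).

    Equal to ``compose_delta(c) * Fa`` up to floating-point rounding; kept
    as an explicit path for cross-checks.
    """
    p_ab = Fa / c.A_contact
    d_vab = c.Cab * p_ab
    d_pth = c.kth * d_vab / c.V0  # magnitude; compression sign absorbed
    return d_pth * c.eta


def pexo_from_force(tm: TransmissionModel, Fa: float) -> float:
    """Extra lung pressure delta*Fa, in delta's declared unit."""
    if Fa < 0:
        raise ValueError(f"assistive force must be >= 0, got {Fa}")
    return tm.delta * Fa


def calibrate_transmission(
    pairs: Sequence[tuple[float, float]] | np.ndarray,
    *,
    delta: float = 0.05,
    delta_unit: DeltaUnit = "cmH2O/N",
) -> CalibrationResult:
    """Fit the linear force-pressure characteristic by ordinary least squares.

    Parameters
    ----------
    pairs : sequence of (Psup_kPa, Fa_N)
        At least three pairs spanning a nonzero pressure range.
    delta, delta_unit :
        Passed through to the returned TransmissionModel (the static fit
        cannot observe delta).

    Returns
    -------
    CalibrationResult
        Slope/intercept with R^2, Pearson r and standard errors. A flat
        force response (zero slope and zero residual variance) is returned
        with ``degenerate=True`` and an undefined (NaN) Pearson r.
    """
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 3:
        raise ValueError("need at least 3 (Psup, Fa) pairs")
    x, y = arr[:, 0], arr[:, 1]
    if np.ptp(x) == 0:
        raise ValueError("all supply pressures identical: singular fit")
    if np.ptp(y) == 0:
        # Flat force response: slope 0, intercept = the constant force;
        # Pearson r is undefined (zero variance in y).
        return CalibrationResult(
            alpha_t=0.0,
            mu=float(y[0]),
            model=None,
            r_squared=0.0,
            pearson_r=float("nan"),
            n=arr.shape[0],
            degenerate=True,
            stderr_slope=0.0,
            stderr_intercept=0.0,
        )
    fit = stats.linregress(x, y)
    slope, intercept = float(fit.slope), float(fit.intercept)
    model = None
    degenerate = True
    if slope > 0 and intercept >= 0:
        model = TransmissionModel(
            alpha_t=slope, mu=intercept, delta=delta, delta_unit=delta_unit
        )
        degenerate = False
    return CalibrationResult(
        alpha_t=slope,
        mu=intercept,
        model=model,
        r_squared=float(fit.rvalue**2),
        pearson_r=float(fit.rvalue),
        n=arr.shape[0],
        degenerate=degenerate,
        stderr_slope=float(fit.stderr),
        stderr_intercept=float(fit.intercept_stderr),
    )
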