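"""Single-compartment lung mechanics and the analytic expiratory waveform family.

The respiratory system is modelled as a first-order resistance-elastance
(R-E) plant acting on the tidal volume excursion ``v`` (expired volume,
positive during expiration)::

    R * dv/dt + E * v = Pmus(t) + Pexo(t)

where ``Pmus`` is the equivalent muscle pressure and ``Pexo`` the extra
lung pressure contributed by the assistive robot through the abdominal
wall. Within one expiration, progress is described by the normalized
expiratory phase ``theta`` in [0, 1]; natural expiratory flow is close to
a half-sine in theta, ``Q(theta) = Q0 * sin(pi * theta)``, and the muscle
pressure that sustains it is a phase-advanced sinusoid

    Pmus(theta) = A * sin(pi*theta + phi),
    A   = Q0 * sqrt(R**2 + (E/pi)**2),
    phi = arctan(-E / (pi * R)),

obtained by summing the resistive drop ``R*Q`` and the elastic recoil
``E*V`` with ``V(theta) = -(Q0/pi) * cos(pi*theta)`` (integration constant
chosen as zero, i.e. volumes referenced to mid-expiration).

The phase lead ``phi`` is negative: pressure must build before flow.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as _signal

__all__ = [
    "LungParams",
    "BreathPattern",
    "MusclePressureProfile",
    "flow_waveform",
    "normalized_volume",
    "physical_tidal_volume",
    "pressure_components",
    "muscle_pressure_profile",
    "simulate_plant",
    "trapezoid_coefficients",
]


@dataclass(frozen=True)
class LungParams:
    """Respiratory plant parameters.

    Parameters
    ----------
    R : float
        Airway resistance, cmH2O*s/L. Must be positive.
    E : float
        Lung elastance (1/compliance), cmH2O/L. Must be positive.
    Vlung0 : float, optional
        Residual lung volume, L. Kept for completeness; the tidal-excursion
        form of the dynamics never uses it.
    PPEEP : float, optional
        Positive end-expiratory pressure, cmH2O. The reduced tidal form
        assumes the static balance ``E*Vlung0 + PPEEP = 0``; a mismatch is
        tolerated but flagged with a warning because it only shifts the
        (unsimulated) absolute-volume operating point.
    """

    R: float
    E: float
    Vlung0: float = 0.0
    PPEEP: float = 0.0

    def __post_init__(self) -> None:
        if not self.R > 0:
            raise ValueError(f"airway resistance R must be > 0, got {self.R}")
        if not self.E > 0:
            raise ValueError(f"lung elastance E must be > 0, got {self.E}")
        if self.Vlung0 < 0:
            raise ValueError(f"residual volume Vlung0 must be >= 0, got {self.Vlung0}")
        if abs(self.E * self.Vlung0 + self.PPEEP) > 1e-9 * max(1.0, self.E):
            warnings.warn(
                "E*Vlung0 + PPEEP != 0: the reduced tidal-excursion dynamics "
                "ignore the absolute-volume offset",
                stacklevel=2,
            )

    @property
    def tau(self) -> float:
        """Mechanical time constant R/E, s."""
        return self.R / self.E


@dataclass(frozen=True)
class BreathPattern:
    """Metronome-paced breathing pattern.

    Q0 is the nominal flow amplitude (L/s), rate the breathing frequency in
    breaths/min, and insp_fraction the share of the cycle spent inspiring.
    """

    Q0: float
    rate: float
    insp_fraction: float = 0.5

    def __post_init__(self) -> None:
        if not self.Q0 > 0:
            raise ValueError(f"flow amplitude Q0 must be > 0, got {self.Q0}")
        if not 1.0 <= self.rate <= 80.0:
            raise ValueError(f"breathing rate must be in [1, 80] /min, got {self.rate}")
        if not 0.0 < self.insp_fraction < 1.0:
            raise ValueError(
                f"insp_fraction must lie in (0, 1), got {self.insp_fraction}"
            )

    @property
    def period(self) -> float:
        """Breath period, s."""
        return 60.0 / self.rate

    @property
    def expiratory_duration(self) -> float:
        """Duration of the expiratory half of the cycle, s."""
        return self.period * (1.0 - self.insp_fraction)


@dataclass(frozen=True)
class MusclePressureProfile:
    """Sinusoidal muscle-pressure waveform ``A_mus * sin(pi*theta + phi)``.

    A_mus is the pressure amplitude in cmH2O; phi the phase lead in radians,
    lying in (-pi/2, 0] for positive R and E.
    """

    A_mus: float
    phi: float

    def __post_init__(self) -> None:
        if self.A_mus < 0:
            raise ValueError(f"pressure amplitude must be >= 0, got {self.A_mus}")
        if not -math.pi / 2 <= self.phi <= 0.0:
            raise ValueError(f"phase lead must lie in [-pi/2, 0], got {self.phi}")

    def __call__(self, theta):
        """Evaluate the profile at expiratory phase theta (scalar or array)."""
        return self.A_mus * np.sin(np.pi * np.asarray(theta) + self.phi)


def _check_theta(theta) -> np.ndarray:
    theta = np.asarray(theta, dtype=float)
    if np.any(theta < 0.0) or np.any(theta > 1.0):
        raise ValueError("expiratory phase theta must lie in [0, 1]")
    return theta


def flow_waveform(theta, Q0: float):
    """Half-sine expiratory flow ``Q0 * sin(pi * theta)``, L/s."""
    if not Q0 > 0:
        raise ValueError(f"flow amplitude Q0 must be > 0, got {Q0}")
    theta = _check_theta(theta)
    out = Q0 * np.sin(np.pi * theta)
    return float(out) if out.ndim == 0 else out


def normalized_volume(theta, Q0: float):
    """Volume change over the expiration in phase units.

    Integral of the half-sine flow over theta (not time):
    ``V(theta) = -(Q0/pi) * cos(pi*theta)``, odd-symmetric about
    theta = 0.5 where it crosses zero.
    """
    theta = _check_theta(theta)
    out = -(Q0 / math.pi) * np.cos(np.pi * theta)
    return float(out) if out.ndim == 0 else out


def physical_tidal_volume(Q0: float, expiratory_duration: float) -> float:
    """Volume in litres expired over one half-sine expiration of given duration.

    The phase-domain ``normalized_volume`` is dimensionally an integral over
    theta; restoring time units gives
    ``integral_0^Te Q0*sin(pi*t/Te) dt = 2*Q0*Te/pi`` litres.
    """
    if expiratory_duration <= 0:
        raise ValueError("expiratory duration must be positive")
    return 2.0 * Q0 * expiratory_duration / math.pi


def pressure_components(theta, Q0: float, lung: LungParams):
    """Resistive and elastic pressure components at phase theta.

    Returns ``(P_R, P_E)`` in cmH2O with ``P_R = R*Q(theta)`` and
    ``P_E = E*V(theta)`` (phase-domain volume).
    """
    theta = _check_theta(theta)
    if Q0 == 0:
        z = np.zeros_like(theta)
        return (float(z), float(z)) if z.ndim == 0 else (z, z)
    p_r = lung.R * flow_waveform(theta, Q0)
    p_e = lung.E * normalized_volume(theta, Q0)
    return p_r, p_e


def muscle_pressure_profile(
    Q0: float, lung: LungParams, *, allow_zero_resistance: bool = False
) -> MusclePressureProfile:
    """Amplitude/phase form of ``P_R + P_E`` for a half-sine expiration.

    ``A_mus = Q0*sqrt(R^2 + (E/pi)^2)`` and ``phi = arctan(-E/(pi*R))``.
    The pure-elastance limit R -> 0 (phi -> -pi/2) is only taken when
    explicitly allowed.
    """
    if lung.R == 0 and not allow_zero_resistance:
        raise ValueError("R = 0 requires allow_zero_resistance=True (phi -> -pi/2)")
    a = Q0 * math.hypot(lung.R, lung.E / math.pi)
    phi = math.atan2(-lung.E / math.pi, lung.R)
    return MusclePressureProfile(A_mus=a, phi=phi)


def trapezoid_coefficients(lung: LungParams, dt: float) -> tuple[float, float]:
    """Coefficients (a1, b) of the trapezoidal update of the R-E plant.

    v[k+1] = a1*v[k] + b*(P[k] + P[k+1])/2, the bilinear discretisation of
    1/(R s + E). With flow read out as Q[k] = (P[k] - E*v[k])/R this update
    satisfies the trapezoidal conservation identity
    (Q[k] + Q[k+1])/2 * dt == v[k+1] - v[k] exactly.
    """
    denom = lung.R / dt + lung.E / 2.0
    return (lung.R / dt - lung.E / 2.0) / denom, 1.0 / denom


def simulate_plant(
    lung: LungParams,
    Pmus,
    Pexo,
    dt: float,
    *,
    method: str = "trapezoid",
):
    """Integrate the first-order plant from v(0)=0 under sampled forcing.

    Parameters
    ----------
    lung : LungParams
    Pmus, Pexo : array_like
        Uniformly sampled pressure series, cmH2O, equal length.
    dt : float
        Sample interval, s. A warning is issued when dt exceeds one tenth
        of the mechanical time constant.
    method : {"trapezoid", "rk4"}
        Fixed-step scheme. "trapezoid" (default) is the bilinear
        discretisation, exact for piecewise-linear forcing at second order
        and samplewise consistent with the pressure balance (flow is read
        out from the balance, not differenced). "rk4" is classical
        Runge-Kutta with linear interpolation of the forcing at half steps.

    Returns
    -------
    volume, flow : ndarray
        Tidal excursion (L) and expiratory flow dv/dt (L/s) at the samples.
    """
    Pmus = np.asarray(Pmus, dtype=float)
    Pexo = np.asarray(Pexo, dtype=float)
    if Pmus.shape != Pexo.shape or Pmus.ndim != 1:
        raise ValueError("Pmus and Pexo must be 1-D arrays of equal length")
    if not dt > 0:
        raise ValueError("dt must be positive")
    if dt > lung.tau / 10.0:
        warnings.warn(
            f"dt={dt:g}s exceeds (R/E)/10={lung.tau / 10.0:g}s; "
            "integration accuracy degrades",
            stacklevel=2,
        )
    p = Pmus + Pexo
    n = p.size
    if method == "trapezoid":
        a1, b = trapezoid_coefficients(lung, dt)
        v = _trapezoid_path(p, a1, b)
        flow = (p - lung.E * v) / lung.R
    elif method == "rk4":
        v = _rk4_path(p, lung.R, lung.E, dt)
        flow = (p - lung.E * v) / lung.R
    else:
        raise ValueError(f"unknown integration method {method!r}")
    return v, flow


def _trapezoid_path(p: np.ndarray, a1: float, b: float) -> np.ndarray:
    # v[k] = a1*v[k-1] + b*(p[k]+p[k-1])/2 with v[0]=0, evaluated as a
    # first-order IIR on the midpoint-forcing sequence.
    u = np.empty_like(p)
    u[0] = 0.0
    u[1:] = 0.5 * (p[1:] + p[:-1])
    return _signal.lfilter([b], [1.0, -a1], u)


def _rk4_path(p: np.ndarray, R: float, E: float, dt: float) -> np.ndarray:
    v = np.empty_like(p)
    v[0] = 0.0
    inv_r = 1.0 / R
    for k in range(p.size - 1):
        p0, p1 = p[k], p[k + 1]
        pm = 0.5 * (p0 + p1)
        y = v[k]
        k1 = inv_r * (p0 - E * y)
        k2 = inv_r * (pm - E * (y + 0.5 * dt * k1))
        k3 = inv_r * (pm - E * (y + 0.5 * dt * k2))
        k4 = inv_r * (p1 - E * (y + dt * k3))
        v[k + 1] = y + dt / 6.0 * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
    return v
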