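"""State-difference least-squares identification of airway resistance and elastance.

The pressure balance of the reduced lung model reads
``R*Q + E*V = Pmus + Pexo``. The muscle pressure is not measurable, but
under metronome-paced breathing it repeats: subtracting a natural session
(group B, Pexo = 0) from an assisted one (group A, Pexo = delta*Fa)
sample by sample cancels Pmus and leaves

    R*(Q_A - Q_B) + E*(V_A - V_B) = delta*Fa,

a linear model in (R, E) solved by ordinary least squares through the
normal equations ``(R, E)^T = (H^T H)^{-1} H^T y`` with H the n x 2
matrix of flow/volume differences and y the assist-pressure samples.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .loop import SessionTrace
from .transmission import TransmissionModel

__all__ = [
    "IdentificationResult",
    "IdentificationError",
    "build_design",
    "identify_RE",
    "identify_from_traces",
]


class IdentificationError(RuntimeError):
    """Raised when the design matrix is singular or too ill-conditioned."""

    def __init__(self, message: str, condition_number: float = float("inf")):
        super().__init__(message)
        self.condition_number = condition_number


@dataclass(frozen=True)
class IdentificationResult:
    """Identified lung parameters with diagnostics.

    R_hat (cmH2O*s/L) and E_hat (cmH2O/L); residual_norm is the 2-norm of
    ``y - H @ (R_hat, E_hat)``; condition_number is cond(H) and is always
    reported; n_samples the number of rows actually used (after the
    noise-floor filter); n_dropped the rows removed by it.
    """

    R_hat: float
    E_hat: float
    residual_norm: float
    condition_number: float
    n_samples: int
    n_dropped: int = 0
    degenerate: bool = False

    def summary(self) -> str:
        lines = [
            "State-difference least-squares identification",
            f"  R_hat [cmH2O*s/L]: {self.R_hat:.6g}",
            f"  E_hat [cmH2O/L]  : {self.E_hat:.6g}",
            f"  residual 2-norm  : {self.residual_norm:.3e}",
            f"  cond(H)          : {self.condition_number:.3e}",
            f"  samples used     : {self.n_samples} ({self.n_dropped} dropped)",
        ]
        if self.degenerate:
            lines.append("  WARNING: degenerate design (no informative rows)")
        return "\n".join(lines)


def _resample_breaths(trace: SessionTrace, points_per_breath: int):
    """Per-breath phase-grid resampling of (Q, V, Fa) by linear interpolation."""
    from .metrics import segment_breaths

    breaths = segment_breaths(trace)
    if not breaths:
        raise IdentificationError("no complete breaths to resample")
    grid = (np.arange(points_per_breath) + 0.5) / points_per_breath
    qs, vs, fas = [], [], []
    for b in breaths:
        idx = np.arange(b.start, b.stop)
        frac = (idx - b.start) / max(b.stop - 1 - b.start, 1)
        qs.append(np.interp(grid, frac, trace.Q[idx]))
        vs.append(np.interp(grid, frac, trace.V[idx]))
        fas.append(np.interp(grid, frac, trace.Fa[idx]))
    return np.concatenate(qs), np.concatenate(vs), np.concatenate(fas), len(breaths)


def build_design(
    pairA: SessionTrace,
    pairB: SessionTrace,
    tm: TransmissionModel,
    *,
    align: str = "time",
    points_per_breath: int = 200,
    noise_floor_frac: float = 0.01,
):
    """Assemble the least-squares system (H, y) from a matched session pair.

    Parameters
    ----------
    pairA, pairB : SessionTrace
        Assisted (A) and natural (B) sessions at the same metronome rate.
    tm : TransmissionModel
        Supplies delta (converted to cmH2O/N) for ``y = delta * Fa``.
    align : {"time", "phase"}
        "time" pairs samples on the shared clock (exact under metronome
        pacing, the default); "phase" resamples each session onto
        ``points_per_breath`` points per breath and pairs breaths in
        order, for sessions whose clocks are not synchronised.
    noise_floor_frac : float
        Rows whose flow AND volume differences both fall below this
        fraction of the respective maximum absolute difference are dropped
        (they only inflate the conditioning).

    Returns
    -------
    H : (n, 2) ndarray, y : (n,) ndarray, info : dict
        info carries ``n_dropped`` and ``degenerate`` (all-zero design).
    """
    delta = tm.delta_cmh2o_per_n
    if align == "time":
        if pairA.n_samples != pairB.n_samples:
            raise ValueError(
                "time alignment requires equal-length traces "
                f"({pairA.n_samples} vs {pairB.n_samples})"
            )
        dq = pairA.Q - pairB.Q
        dv = pairA.V - pairB.V
        y = delta * pairA.Fa
    elif align == "phase":
        qa, va, fa_a, nba = _resample_breaths(pairA, points_per_breath)
        qb, vb, _, nbb = _resample_breaths(pairB, points_per_breath)
        nb = min(nba, nbb)
        m = nb * points_per_breath
        if m == 0:
            raise IdentificationError("no breaths after resampling")
        dq = qa[:m] - qb[:m]
        dv = va[:m] - vb[:m]
        y = delta * fa_a[:m]
    else:
        raise ValueError(f"unknown alignment {align!r}")

    max_dq = float(np.max(np.abs(dq)))
    max_dv = float(np.max(np.abs(dv)))
    if max_dq == 0.0 and max_dv == 0.0:
        return (
            np.column_stack([dq, dv]),
            np.asarray(y, dtype=float),
            {"n_dropped": 0, "degenerate": True},
        )
    keep = (np.abs(dq) >= noise_floor_frac * max_dq) | (
        np.abs(dv) >= noise_floor_frac * max_dv
    )
    n_dropped = int(np.size(keep) - np.count_nonzero(keep))
    H = np.column_stack([dq[keep], dv[keep]])
    return H, np.asarray(y, dtype=float)[keep], {"n_dropped": n_dropped, "degenerate": False}


def identify_RE(
    H: np.ndarray,
    y: np.ndarray,
    *,
    cond_max: float = 1e8,
    n_dropped: int = 0,
) -> IdentificationResult:
    """Solve the normal equations for (R, E) with conditioning diagnostics.

    Raises IdentificationError (carrying the condition number) when H is
    singular or cond(H) exceeds ``cond_max``; there is no silent
    pseudo-inverse fallback.
    """
    H = np.asarray(H, dtype=float)
    y = np.asarray(y, dtype=float)
    if H.ndim != 2 or H.shape[1] != 2 or H.shape[0] != y.size:
        raise ValueError("H must be n x 2 with matching y")
    if H.shape[0] < 2:
        raise ValueError("need at least 2 samples")
    if not np.any(H):
        raise IdentificationError("design matrix is identically zero", float("inf"))
    cond = float(np.linalg.cond(H))
    if not np.isfinite(cond) or cond > cond_max:
        raise IdentificationError(
            f"design matrix too ill-conditioned (cond(H) = {cond:.3e} > {cond_max:.1e})",
            cond,
        )
    gram = H.T @ H
    rhs = H.T @ y
    theta = np.linalg.solve(gram, rhs)
    residual = float(np.linalg.norm(y - H @ theta))
    return IdentificationResult(
        R_hat=float(theta[0]),
        E_hat=float(theta[1]),
        residual_norm=residual,
        condition_number=cond,
        n_samples=int(H.shape[0]),
        n_dropped=n_dropped,
    )


def identify_from_traces(
    pairA: SessionTrace,
    pairB: SessionTrace,
    tm: TransmissionModel,
    *,
    align: str = "time",
    cond_max: float = 1e8,
    **kwargs,
) -> IdentificationResult:
    """build_design + identify_RE in one call."""
    H, y, info = build_design(pairA, pairB, tm, align=align, **kwargs)
    if info["degenerate"]:
        raise IdentificationError(
            "identical traces with zero assist: nothing to identify", float("inf")
        )
    return identify_RE(H, y, cond_max=cond_max, n_dropped=info["n_dropped"])
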