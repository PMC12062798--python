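"""Respiratory-function metrics and cohort statistics.

From a session trace: Peak Expiratory Flow (PEF, session maximum of
expiratory flow), Mean Tidal Volume (MTV, mean over complete breaths of
the end-expiratory minus end-inspiratory volume), Minute Ventilation (MV,
expired volume normalised to one minute) and its phase split MV_e / MV_i.
MV here is expiration-side by definition (MV_i is reported separately);
conventions differ across the literature, so this is stated prominently.

Across a cohort: per-metric percent improvement baseline -> assisted and
paired significance (two-sided paired t-test by default, Wilcoxon as an
option) with the conventional star notation (* p<0.05, ** p<0.01,
*** p<0.001).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .loop import SessionTrace

__all__ = [
    "Breath",
    "MetricsReport",
    "ImprovementReport",
    "segment_breaths",
    "compute_metrics",
    "improvement_rates",
    "paired_significance",
    "cohort_improvement",
    "significance_stars",
]

METRIC_NAMES = ("pef", "mtv", "mv")


@dataclass(frozen=True)
class Breath:
    """One complete breath: sample range [start, stop) beginning at
    expiration onset, with the inspiration starting at ``insp_start``."""

    start: int
    insp_start: int
    stop: int


@dataclass(frozen=True)
class MetricsReport:
    """Session-level ventilation metrics (all volumes in L, flows in L/s)."""

    pef: float
    mtv: float
    mv: float
    mv_insp: float
    mv_exp: float
    n_breaths: int
    rate_observed: float

    def __post_init__(self) -> None:
        for name in ("pef", "mtv", "mv", "mv_insp", "mv_exp"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.n_breaths < 1:
            raise ValueError("need at least one complete breath")
        expected = self.mtv * self.rate_observed
        if expected > 0 and abs(self.mv - expected) > 0.02 * expected:
            warnings.warn(
                f"MV ({self.mv:.3f} L/min) deviates from MTV*rate "
                f"({expected:.3f} L/min) by more than 2%",
                stacklevel=2,
            )

    def summary(self) -> str:
        return (
            f"PEF {self.pef:.3f} L/s | MTV {self.mtv:.3f} L | "
            f"MV {self.mv:.3f} L/min (insp {self.mv_insp:.3f} / exp {self.mv_exp:.3f}) | "
            f"{self.n_breaths} breaths at {self.rate_observed:.1f}/min"
        )


@dataclass(frozen=True)
class ImprovementReport:
    """Cohort improvement baseline -> assisted.

    percent: per-metric mean percent change across subjects;
    per_subject: rows of per-subject percent changes;
    p_values / stars: paired-test results per metric.
    """

    percent: dict[str, float]
    per_subject: dict[str, np.ndarray]
    p_values: dict[str, float] = field(default_factory=dict)
    stars: dict[str, str] = field(default_factory=dict)
    test: str = "ttest"

    def summary(self) -> str:
        lines = ["Metric improvement (assisted vs baseline)"]
        for m in METRIC_NAMES:
            p = self.p_values.get(m, float("nan"))
            lines.append(
                f"  {m.upper():<4}: {self.percent[m]:+7.2f}%  p={p:.4g} {self.stars.get(m, '')}"
            )
        return "\n".join(lines)


def _smooth(x: np.ndarray, window: int = 5) -> np.ndarray:
    if window <= 1:
        return x
    kernel = np.ones(window) / window
    return np.convolve(x, kernel, mode="same")


def segment_breaths(
    trace: SessionTrace,
    hysteresis: float | None = None,
    *,
    min_phase_samples: int | None = None,
) -> list[Breath]:
    """Offline segmentation of a trace into complete breaths.

    A breath runs from one expiration onset to the next, with the
    intervening inspiration onset recorded. Transitions are detected by
    hysteresis on the smoothed flow (expiratory flow positive), debounced
    by ``min_phase_samples``; partial first/last breaths are discarded.
    Default hysteresis is 2% of the peak absolute flow.
    """
    q = _smooth(np.asarray(trace.Q, dtype=float))
    n = q.size
    if n == 0:
        return []
    peak = float(np.max(np.abs(q)))
    if peak == 0.0:
        return []
    if hysteresis is None:
        hysteresis = 0.02 * peak
    if min_phase_samples is None:
        min_phase_samples = max(int(0.05 * trace.fs), 1)

    exp_onsets: list[int] = []
    insp_onsets: list[int] = []
    label = "expiration" if q[0] > 0 else "inspiration"
    if label == "expiration" and q[0] <= hysteresis:
        # the record begins right at an expiration onset (flow still
        # within the hysteresis band); count it
        exp_onsets.append(0)
    since = 0
    for k in range(n):
        since += 1
        if label == "expiration":
            if since >= min_phase_samples and q[k] < -hysteresis:
                label = "inspiration"
                insp_onsets.append(k)
                since = 0
        else:
            if since >= min_phase_samples and q[k] > hysteresis:
                label = "expiration"
                exp_onsets.append(k)
                since = 0

    breaths: list[Breath] = []
    for i in range(len(exp_onsets) - 1):
        start, stop = exp_onsets[i], exp_onsets[i + 1]
        mids = [j for j in insp_onsets if start < j < stop]
        if not mids:
            continue
        breaths.append(Breath(start=start, insp_start=mids[0], stop=stop))
    return breaths


def compute_metrics(
    trace: SessionTrace,
    *,
    hysteresis: float | None = None,
    per_breath_pef: bool = False,
) -> MetricsReport:
    """Ventilation metrics over the complete breaths of a session.

    PEF is the session maximum of expiratory flow (set ``per_breath_pef``
    to average per-breath maxima instead); tidal volume per breath is the
    end-expiratory minus end-inspiratory volume (max minus min of the
    volume curve within the breath); MV is total expired volume over the
    complete-breath span, normalised to one minute.
    """
    breaths = segment_breaths(trace, hysteresis)
    if not breaths:
        raise ValueError("no complete breath in trace")
    q = np.asarray(trace.Q, dtype=float)
    v = np.asarray(trace.V, dtype=float)
    dt = trace.dt

    tidal_volumes = []
    pef_per_breath = []
    expired = 0.0
    inspired = 0.0
    for b in breaths:
        sl = slice(b.start, b.stop)
        tidal_volumes.append(float(np.max(v[sl]) - np.min(v[sl])))
        pef_per_breath.append(float(np.max(q[sl])))
        qb = q[sl]
        expired += float(np.sum(qb[qb > 0])) * dt
        inspired += float(-np.sum(qb[qb < 0])) * dt

    span = (breaths[-1].stop - breaths[0].start) * dt  # seconds
    minutes = span / 60.0
    n_b = len(breaths)
    pef = float(np.mean(pef_per_breath)) if per_breath_pef else float(max(pef_per_breath))
    return MetricsReport(
        pef=pef,
        mtv=float(np.mean(tidal_volumes)),
        mv=expired / minutes,
        mv_insp=inspired / minutes,
        mv_exp=expired / minutes,
        n_breaths=n_b,
        rate_observed=n_b / minutes,
    )


def improvement_rates(
    baseline: MetricsReport, assisted: MetricsReport
) -> dict[str, float]:
    """Percent change (assisted - baseline)/baseline * 100 per metric."""
    out = {}
    for m in METRIC_NAMES:
        b = getattr(baseline, m)
        if b <= 0:
            raise ValueError(f"baseline {m} must be positive")
        out[m] = (getattr(assisted, m) - b) / b * 100.0
    return out


def significance_stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def paired_significance(
    baseline: Sequence[float],
    assisted: Sequence[float],
    *,
    test: str = "ttest",
) -> tuple[float, str, bool]:
    """Two-sided paired test across subjects.

    Returns (p_value, stars, degenerate). ``degenerate`` is set when the
    paired differences have zero variance (identical vectors give p = 1
    with no stars; a constant nonzero shift admits no finite t statistic
    and is flagged rather than starred).
    """
    b = np.asarray(baseline, dtype=float)
    a = np.asarray(assisted, dtype=float)
    if b.shape != a.shape or b.ndim != 1:
        raise ValueError("baseline and assisted must be equal-length 1-D vectors")
    if b.size < 3:
        raise ValueError("need at least 3 pairs")
    d = a - b
    if np.ptp(d) == 0.0:
        if d[0] == 0.0:
            return 1.0, "", True
        return float("nan"), "", True
    if test == "ttest":
        p = float(stats.ttest_rel(a, b).pvalue)
    elif test == "wilcoxon":
        p = float(stats.wilcoxon(a, b).pvalue)
    else:
        raise ValueError(f"unknown test {test!r}")
    return p, significance_stars(p), False


def cohort_improvement(
    baselines: Sequence[MetricsReport],
    assisteds: Sequence[MetricsReport],
    *,
    test: str = "ttest",
) -> ImprovementReport:
    """Aggregate per-subject improvements with paired significance.

    The cohort-level rate per metric is the arithmetic mean of the
    per-subject percent changes; significance is tested on the per-subject
    metric values (baseline vs assisted).
    """
    if len(baselines) != len(assisteds) or not baselines:
        raise ValueError("need matched non-empty baseline/assisted report lists")
    per_subject = {
        m: np.array(
            [improvement_rates(b, a)[m] for b, a in zip(baselines, assisteds)]
        )
        for m in METRIC_NAMES
    }
    percent = {m: float(np.mean(v)) for m, v in per_subject.items()}
    p_values: dict[str, float] = {}
    stars: dict[str, str] = {}
    if len(baselines) >= 3:
        for m in METRIC_NAMES:
            b = [getattr(r, m) for r in baselines]
            a = [getattr(r, m) for r in assisteds]
            p, s, _ = paired_significance(b, a, test=test)
            p_values[m] = p
            stars[m] = s
    return ImprovementReport(
        percent=percent, per_subject=per_subject, p_values=p_values, stars=stars, test=test
    )
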