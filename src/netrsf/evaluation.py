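"""Model evaluation: Harrell's C-index, mean-cutoff stratification,
Kaplan-Meier curves, and the two-group log-rank test.

The concordance index follows the standard Harrell convention: a pair is
usable iff the smaller observed time carries an event (equal observed
times are usable only when exactly one is an event); tied risk scores
count 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank

__all__ = [
    "ConcordanceResult",
    "StrataAssignment",
    "LogrankResult",
    "KMCurve",
    "concordance_index",
    "stratify_by_mean",
    "logrank_test",
    "km_curve",
]


@dataclass
class ConcordanceResult:
    c_index: float
    usable_pairs: int


@dataclass
class StrataAssignment:
    """Per-sample high/low labels; high iff risk strictly exceeds the cutoff."""

    labels: np.ndarray  # array of "high"/"low"
    cutoff: float

    @property
    def n_high(self) -> int:
        return int((self.labels == "high").sum())

    @property
    def n_low(self) -> int:
        return int((self.labels == "low").sum())


@dataclass
class LogrankResult:
    statistic: float
    p: float


@dataclass
class KMCurve:
    """Product-limit survival estimate: S(0)=1, nonincreasing steps."""

    times: np.ndarray
    survival: np.ndarray
    median: float | None  # None = median survival not reached


def concordance_index(risk, times, events) -> ConcordanceResult:
    """Harrell's C over all usable pairs (vectorized pair enumeration)."""
    risk = np.asarray(risk, dtype=float)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events).astype(bool)
    n = len(risk)
    if not (len(times) == len(events) == n):
        raise ValueError("risk, times and events must have equal length")
    t_i, t_j = times[:, None], times[None, :]
    e_i = events[:, None]
    # pair (i, j): i is the shorter-surviving member with an event
    shorter_event = (t_i < t_j) & e_i
    tied_time = (t_i == t_j) & e_i & ~events[None, :]
    usable = shorter_event | tied_time
    r_i, r_j = risk[:, None], risk[None, :]
    concordant = usable & (r_i > r_j)
    tied_risk = usable & (r_i == r_j)
    # remove i==j diagonal (never usable: tied_time needs event mismatch)
    m = int(usable.sum())
    if m == 0:
        raise ValueError("no usable pairs under censoring")
    c = (concordant.sum() + 0.5 * tied_risk.sum()) / m
    return ConcordanceResult(float(c), m)


def stratify_by_mean(train_risk, apply_risk) -> StrataAssignment:
    """High/low strata with the cutoff fixed at the mean of *training* risk.

    The same cutoff is reused for any later cohort passed as ``apply_risk``;
    a sample whose risk equals the cutoff exactly goes to the low group.
    """
    train_risk = np.asarray(train_risk, dtype=float)
    if train_risk.size == 0:
        raise ValueError("training risk is empty")
    cutoff = float(train_risk.mean())
    apply_risk = np.asarray(apply_risk, dtype=float)
    labels = np.where(apply_risk > cutoff, "high", "low")
    return StrataAssignment(labels, cutoff)


def logrank_test(times, events, groups) -> LogrankResult:
    """Two-group log-rank test (chi-square with 1 df)."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events).astype(int)
    groups = np.asarray(groups)
    labels = np.unique(groups)
    if len(labels) != 2:
        raise ValueError(f"exactly two nonempty groups required, found {len(labels)}")
    if events.sum() == 0:
        raise ValueError("log-rank test needs at least one event")
    a = groups == labels[0]
    res = _ll_logrank(times[a], times[~a], events[a], events[~a])
    return LogrankResult(float(res.test_statistic), float(res.p_value))


def km_curve(times, events) -> KMCurve:
    """Kaplan-Meier product-limit estimate with median survival if reached.

    Deaths are processed before censorings at a tied timestamp (the
    standard at-risk convention), so a sample censored at a death time
    still counts as at risk for that death.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events).astype(int)
    if times.size == 0:
        raise ValueError("empty survival input")
    kmf = KaplanMeierFitter()
    kmf.fit(times, events)
    grid = kmf.survival_function_.index.to_numpy(dtype=float)
    surv = kmf.survival_function_.iloc[:, 0].to_numpy(dtype=float)
    med = kmf.median_survival_time_
    median = None if np.isinf(med) else float(med)
    return KMCurve(grid, surv, median)
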