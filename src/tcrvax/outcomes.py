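"""Exploratory outcome stratification: quantile split, Kaplan–Meier, log-rank.

The trial's correlative analysis splits subjects at the 25th percentile of
an immune-response score (pooled-average or tumor-matched maximal fold
change) and compares disease-free survival between the lowest quartile and
the upper three quartiles with the Kaplan–Meier estimator and a two-group
log-rank test.  Cox hazard-ratio fits are deliberately left to standard
survival packages and are not wrapped here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank

__all__ = [
    "SurvivalRecord",
    "KmEstimate",
    "stratify_by_quantile",
    "km_estimate",
    "logrank_test",
]


@dataclass(frozen=True)
class SurvivalRecord:
    """One subject's follow-up: months from first vaccine dose, event flag."""

    subject_id: str
    time: float
    event: bool
    group: str | None = None

    def __post_init__(self) -> None:
        if not self.time > 0:
            raise ValueError(f"time must be > 0, got {self.time}")


@dataclass
class KmEstimate:
    """Product-limit survival curve and its median.

    ``median`` is the earliest time with S(t) ≤ 0.5, or ``None`` when the
    curve never drops that far (median not reached).
    """

    survival: pd.DataFrame  # columns: time, survival
    median: float | None

    def at(self, t: float) -> float:
        """S(t): survival probability at time ``t`` (right-continuous)."""
        s = self.survival[self.survival["time"] <= t]["survival"]
        return float(s.iloc[-1]) if len(s) else 1.0


def stratify_by_quantile(scores: Mapping[str, float], q: float = 0.25) -> dict[str, str]:
    """Split subjects at the q-th percentile of their scores.

    The percentile uses the linear-interpolation convention (numpy's
    default); scores at or below the threshold go to ``"low"``, the rest
    to ``"high"``.  With q = 0.25 and 12 subjects this reproduces a
    3-versus-9 lowest-quartile split.  When every score is identical the
    split is degenerate: a warning is issued and all subjects are
    ``"high"``.
    """
    if not 0 < q < 1:
        raise ValueError("q must be in (0, 1)")
    if len(scores) < 2:
        raise ValueError("stratification needs >= 2 subjects")
    values = np.array(list(scores.values()), dtype=float)
    if np.all(values == values[0]):
        warnings.warn("all scores identical: degenerate stratification, all high", stacklevel=2)
        return {s: "high" for s in scores}
    threshold = float(np.quantile(values, q))
    return {s: ("low" if v <= threshold else "high") for s, v in scores.items()}


def _to_arrays(records: Iterable[SurvivalRecord]) -> tuple[np.ndarray, np.ndarray]:
    recs = list(records)
    if not recs:
        raise ValueError("need at least one survival record")
    times = np.array([r.time for r in recs], dtype=float)
    events = np.array([r.event for r in recs], dtype=bool)
    return times, events


def km_estimate(records: Iterable[SurvivalRecord]) -> KmEstimate:
    """Kaplan–Meier product-limit estimate with median survival."""
    times, events = _to_arrays(records)
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    surv = kmf.survival_function_.reset_index()
    surv.columns = ["time", "survival"]
    median = float(kmf.median_survival_time_)
    return KmEstimate(survival=surv, median=None if np.isinf(median) else median)


def logrank_test(
    group_a: Iterable[SurvivalRecord], group_b: Iterable[SurvivalRecord]
) -> tuple[float, float]:
    """Two-group log-rank test; returns (chi-square statistic, p-value).

    Raises
    ------
    ValueError
        When either group is empty.
    """
    ta, ea = _to_arrays(group_a)
    tb, eb = _to_arrays(group_b)
    res = _ll_logrank(ta, tb, event_observed_A=ea, event_observed_B=eb)
    return float(res.test_statistic), float(res.p_value)
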