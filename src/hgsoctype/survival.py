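"""Kaplan-Meier estimation, median survival, and the log-rank test.

Thin, typed layer over lifelines with the conventions fixed: censored
observations tied with events are still at risk at that time (events
first); the median is the first event time at which S(t) <= 0.5; the
log-rank statistic uses the hypergeometric variance with ties.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from lifelines.utils import restricted_mean_survival_time

__all__ = [
    "SurvivalRecord",
    "KMCurve",
    "read_survival_table",
    "km_estimate",
    "median_survival",
    "restricted_mean",
    "logrank_test",
    "compare_groups",
]


@dataclass(frozen=True)
class SurvivalRecord:
    """One subject's follow-up: time in months, event flag, group label."""

    sample_id: str
    time: float
    event: int
    group: str = ""

    def __post_init__(self) -> None:
        if not np.isfinite(self.time) or self.time <= 0:
            raise ValueError(f"{self.sample_id}: time must be finite and positive")
        if self.event not in (0, 1):
            raise ValueError(f"{self.sample_id}: event must be 0 or 1")


@dataclass(frozen=True)
class KMCurve:
    """Product-limit estimate evaluated just after each event time."""

    event_times: np.ndarray  # distinct event times, ascending
    survival: np.ndarray  # S(t) after each event time
    at_risk: np.ndarray  # subjects at risk at each event time
    events: np.ndarray  # events at each event time
    n_subjects: int

    def survival_at(self, t: float) -> float:
        """S(t) with S = 1 before the first event."""
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def read_survival_table(path: str | Path) -> list[SurvivalRecord]:
    """Read a TSV with columns sample, time_months, event[, group]."""
    df = pd.read_csv(path, sep="\t")
    required = {"sample", "time_months", "event"}
    if not required <= set(df.columns):
        raise ValueError(f"survival table must have columns {sorted(required)}")
    has_group = "group" in df.columns
    return [
        SurvivalRecord(
            str(r.sample),
            float(r.time_months),
            int(r.event),
            str(r.group) if has_group else "",
        )
        for r in df.itertuples()
    ]


def _times_events(records: list[SurvivalRecord]) -> tuple[np.ndarray, np.ndarray]:
    return (
        np.array([r.time for r in records], dtype=float),
        np.array([r.event for r in records], dtype=int),
    )


def km_estimate(records: list[SurvivalRecord]) -> KMCurve:
    """Kaplan-Meier product-limit estimator."""
    if not records:
        raise ValueError("no survival records")
    times, events = _times_events(records)
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    table = kmf.event_table
    ev = table[table["observed"] > 0]
    event_times = ev.index.to_numpy(dtype=float)
    surv = np.array(
        [float(kmf.survival_function_at_times(t).iloc[0]) for t in event_times]
    )
    return KMCurve(
        event_times=event_times,
        survival=surv,
        at_risk=ev["at_risk"].to_numpy(dtype=int),
        events=ev["observed"].to_numpy(dtype=int),
        n_subjects=len(records),
    )


def median_survival(c: KMCurve) -> float | None:
    """Smallest event time with S(t) <= 0.5, or None ("not reached")."""
    hit = np.nonzero(c.survival <= 0.5)[0]
    return float(c.event_times[hit[0]]) if hit.size else None


def restricted_mean(records: list[SurvivalRecord], horizon: float | None = None) -> float:
    """Restricted mean survival time up to ``horizon``.

    Defaults to the largest observed time, the usual reading when a "mean
    survival" is quoted without a horizon.
    """
    times, events = _times_events(records)
    if horizon is None:
        horizon = float(times.max())
    kmf = KaplanMeierFitter().fit(times, event_observed=events)
    return float(restricted_mean_survival_time(kmf, t=horizon))


def logrank_test(
    a: list[SurvivalRecord], b: list[SurvivalRecord]
) -> tuple[float, float]:
    """Two-group log-rank test; returns (chi-square statistic, p-value)."""
    if not a or not b:
        raise ValueError("both groups must be non-empty")
    ta, ea = _times_events(a)
    tb, eb = _times_events(b)
    if ea.sum() + eb.sum() == 0:
        raise ValueError("log-rank test requires at least one event")
    res = _ll_logrank(ta, tb, event_observed_A=ea, event_observed_B=eb)
    return float(res.test_statistic), float(res.p_value)


def compare_groups(records: list[SurvivalRecord]) -> dict:
    """Per-group KM curves, medians, and the log-rank comparison.

    Requires exactly two distinct group labels.  Returns a dict with keys
    ``groups`` (label -> {curve, median, n, events}), ``chi_square``, and
    ``p_value``.
    """
    labels = sorted({r.group for r in records})
    if len(labels) != 2:
        raise ValueError(f"expected exactly 2 group labels, got {labels}")
    split = {lab: [r for r in records if r.group == lab] for lab in labels}
    chi2, p = logrank_test(split[labels[0]], split[labels[1]])
    out = {"groups": {}, "chi_square": chi2, "p_value": p}
    for lab in labels:
        curve = km_estimate(split[lab])
        out["groups"][lab] = {
            "curve": curve,
            "median": median_survival(curve),
            "n": len(split[lab]),
            "events": int(sum(r.event for r in split[lab])),
        }
    return out
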