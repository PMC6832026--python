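"""Day-level evaluation of HF alerts against clinical events.

Every evaluable monitoring day is labeled against the patient's events using
two windows that both end the day before an event (the event day itself is
not a monitored pre-event day):

* the *detection window* of D days (default 30) before an event — an alert
  anywhere in it counts as a true positive, since fluid accumulation can
  begin weeks before the clinical event;
* the *critical window* of W days (default 3) before an event — a day
  without an alert here is a false negative, the missed minimum actionable
  period.

Label rules, with window membership taken as a union over the patient's
events: alert & in-detection -> TP; alert & not in-detection -> FP;
no alert & in-critical -> FN; otherwise TN.  Counts are pooled over patients
and summarized as sensitivity TP/(TP+FN), specificity TN/(TN+FP) and
accuracy, with Wilson score 95% confidence intervals on the pooled day
counts by default (a patient-level cluster bootstrap is available, since
days within a patient are correlated).

By default only days on which the detector can in principle alert are
evaluable (day learning_days + run_length onward); counting the warm-up days
as true negatives would inflate specificity by construction.  Events after
the monitoring period still contribute the part of their windows that
intersects the evaluable range; an event whose detection window misses the
range entirely is not evaluable, which is why the number of subjects with
evaluable events can grow with D.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint

from .simulate import ClinicalEvent

__all__ = [
    "WindowConfig",
    "ConfusionCounts",
    "PerformanceResult",
    "label_days",
    "pool_counts",
    "performance",
    "lead_times",
    "sensitivity_grid",
    "composite_event_counts",
    "cluster_bootstrap_ci",
]

TP, FP, TN, FN = "TP", "FP", "TN", "FN"


@dataclass(frozen=True)
class WindowConfig:
    detection_window: int = 30
    critical_window: int = 3

    def __post_init__(self) -> None:
        if not (1 <= self.critical_window <= self.detection_window):
            raise ValueError(
                "need 1 <= critical_window <= detection_window "
                f"(got W={self.critical_window}, D={self.detection_window})"
            )


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int = 0
    fp: int = 0
    tn: int = 0
    fn: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp, self.fp + other.fp, self.tn + other.tn, self.fn + other.fn
        )

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @classmethod
    def from_labels(cls, labels) -> "ConfusionCounts":
        counts = pd.Series(list(labels)).value_counts()
        return cls(
            tp=int(counts.get(TP, 0)),
            fp=int(counts.get(FP, 0)),
            tn=int(counts.get(TN, 0)),
            fn=int(counts.get(FN, 0)),
        )


@dataclass(frozen=True)
class PerformanceResult:
    """Pooled day-level operating characteristics.

    Rates are fractions in [0, 1]; a rate whose denominator is zero is None
    (an explicit undefined marker, never a silent zero), as is its CI.
    """

    counts: ConfusionCounts
    sensitivity: float | None
    specificity: float | None
    accuracy: float | None
    sensitivity_ci: tuple[float, float] | None
    specificity_ci: tuple[float, float] | None
    accuracy_ci: tuple[float, float] | None
    n_subjects_evaluated: int | None = None
    n_subjects_with_evaluable_events: int | None = None
    mean_lead_days: float | None = None
    median_lead_days: float | None = None


def _in_any_window(day: int, event_days, width: int) -> bool:
    return any(e - width <= day <= e - 1 for e in event_days)


def label_days(
    alert_by_day: dict[int, bool],
    events: list[ClinicalEvent],
    windows: WindowConfig,
    evaluable_days,
) -> pd.DataFrame:
    """Label each evaluable day TP/FP/TN/FN for one patient.

    ``alert_by_day`` maps day -> alert flag (days missing from the mapping
    carry no alert).  ``evaluable_days`` is the iterable of day numbers to
    label.  Returns a table with columns day, alert, label.
    """
    event_days = [e.day for e in events]
    d_width, w_width = windows.detection_window, windows.critical_window
    records = []
    for day in evaluable_days:
        day = int(day)
        alert = bool(alert_by_day.get(day, False))
        in_detection = _in_any_window(day, event_days, d_width)
        in_critical = _in_any_window(day, event_days, w_width)
        if alert:
            label = TP if in_detection else FP
        else:
            label = FN if in_critical else TN
        records.append((day, alert, label))
    return pd.DataFrame(records, columns=["day", "alert", "label"])


def pool_counts(tables: list[pd.DataFrame]) -> ConfusionCounts:
    """Element-wise sum of per-patient day labels into pooled counts."""
    total = ConfusionCounts()
    for t in tables:
        total = total + ConfusionCounts.from_labels(t["label"])
    return total


def _rate_and_ci(successes: int, trials: int, ci_method: str):
    if trials == 0:
        return None, None
    rate = successes / trials
    lo, hi = proportion_confint(successes, trials, alpha=0.05, method=ci_method)
    return rate, (float(lo), float(hi))


def performance(counts: ConfusionCounts, ci_method: str = "wilson") -> PerformanceResult:
    """Sensitivity, specificity and accuracy with 95% CIs on pooled counts."""
    sens, sens_ci = _rate_and_ci(counts.tp, counts.tp + counts.fn, ci_method)
    spec, spec_ci = _rate_and_ci(counts.tn, counts.tn + counts.fp, ci_method)
    acc, acc_ci = _rate_and_ci(counts.tp + counts.tn, counts.total, ci_method)
    return PerformanceResult(
        counts=counts,
        sensitivity=sens,
        specificity=spec,
        accuracy=acc,
        sensitivity_ci=sens_ci,
        specificity_ci=spec_ci,
        accuracy_ci=acc_ci,
    )


def lead_times(
    per_patient: list[tuple[dict[int, bool], list[ClinicalEvent]]],
    windows: WindowConfig,
) -> tuple[float | None, float | None, list[int]]:
    """Alert-to-event lead times over all events with an in-window alert.

    For each event, the lead is event_day minus the *first* alert day inside
    that event's detection window; events with no in-window alert are
    skipped.  Returns (mean, median, leads); (None, None, []) when no event
    has an in-window alert.
    """
    leads: list[int] = []
    d_width = windows.detection_window
    for alert_by_day, events in per_patient:
        alert_days = sorted(d for d, a in alert_by_day.items() if a)
        for e in events:
            in_window = [d for d in alert_days if e.day - d_width <= d <= e.day - 1]
            if in_window:
                leads.append(e.day - in_window[0])
    if not leads:
        return None, None, []
    return float(np.mean(leads)), float(np.median(leads)), leads


def _evaluable_events(
    events: list[ClinicalEvent], evaluable_days, detection_window: int
) -> list[ClinicalEvent]:
    dmin, dmax = min(evaluable_days), max(evaluable_days)
    return [
        e
        for e in events
        if e.day - detection_window <= dmax and e.day - 1 >= dmin
    ]


def sensitivity_grid(
    per_patient: list[tuple[dict[int, bool], list[ClinicalEvent]]],
    evaluable_days,
    detection_windows=(14, 21, 30),
    critical_windows=(3, 7, 14),
    ci_method: str = "wilson",
) -> pd.DataFrame:
    """Operating characteristics over a grid of (D, W) window choices.

    One row per valid (detection_window, critical_window) cell, with pooled
    sensitivity/specificity/accuracy and subject counts.  Per cell, an event
    is evaluable iff its detection window intersects the evaluable day
    range, so subjects-with-events can grow with D.
    """
    evaluable_days = list(evaluable_days)
    rows = []
    for d_width in detection_windows:
        for w_width in critical_windows:
            if w_width > d_width:
                continue
            windows = WindowConfig(detection_window=d_width, critical_window=w_width)
            tables = []
            n_with_events = 0
            for alert_by_day, events in per_patient:
                tables.append(label_days(alert_by_day, events, windows, evaluable_days))
                if _evaluable_events(events, evaluable_days, d_width):
                    n_with_events += 1
            perf = performance(pool_counts(tables), ci_method)
            rows.append(
                {
                    "detection_window": d_width,
                    "critical_window": w_width,
                    "n_subjects": len(per_patient),
                    "n_subjects_with_events": n_with_events,
                    "sensitivity": perf.sensitivity,
                    "specificity": perf.specificity,
                    "accuracy": perf.accuracy,
                    "tp": perf.counts.tp,
                    "fp": perf.counts.fp,
                    "tn": perf.counts.tn,
                    "fn": perf.counts.fn,
                }
            )
    return pd.DataFrame(rows)


def composite_event_counts(events_df: pd.DataFrame) -> dict:
    """Composite-endpoint tally from an events table (patient_id, day, type).

    The composite endpoint is an unplanned HF readmission or a diuretic
    uptitration; the composite total is the sum of the two arms.  Also
    reports the number of distinct patients with at least one event.
    """
    by_type = events_df["type"].value_counts()
    n_readmission = int(by_type.get("readmission", 0))
    n_uptitration = int(by_type.get("diuretic_uptitration", 0))
    return {
        "n_readmission": n_readmission,
        "n_uptitration": n_uptitration,
        "n_composite": n_readmission + n_uptitration,
        "n_patients_with_events": int(events_df["patient_id"].nunique()),
    }


def cluster_bootstrap_ci(
    tables: list[pd.DataFrame],
    metric: str = "sensitivity",
    n_boot: int = 1000,
    seed: int = 0,
) -> tuple[float, float] | None:
    """Patient-level bootstrap percentile CI for one pooled rate.

    Resamples whole patients with replacement, recomputing the pooled metric
    each time; respects within-patient day correlation that the pooled
    Wilson interval ignores.  Returns None when the metric is undefined in
    too many resamples (> 50%).
    """
    rng = np.random.default_rng(seed)
    n = len(tables)
    stats = []
    for _ in range(n_boot):
        idx = rng.integers(0, n, n)
        perf = performance(pool_counts([tables[i] for i in idx]))
        value = getattr(perf, metric)
        if value is not None:
            stats.append(value)
    if len(stats) < n_boot / 2:
        return None
    return float(np.percentile(stats, 2.5)), float(np.percentile(stats, 97.5))
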