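"""Patient-adaptive heart-failure alert detector.

The detector is tailored to each patient.  The expected-normal bioimpedance
level is learned as the mean of the analyzable measurements over the first
``learning_days`` post-discharge days (default 4), and the patient's normal
range is the multiplicative band ``level * (1 - h, 1 + h)`` with half-width
fraction ``h`` (default 0.10, standing in for population knowledge of normal
day-to-day variability of the index in stable ambulatory patients).

Each subsequent analyzable day is classified against the current band:
``normal``, ``abnormal_low`` or ``abnormal_high`` (closed interval: boundary
values are normal).  After a normal day the level adapts by an exponential
update ``level <- (1 - a) * level + a * index``; abnormal days never move the
level, so a developing decompensation cannot drag its own reference down.
An HF alert is raised on every day that ends a run of at least ``run_length``
(default 3) consecutive calendar days, each with an analyzable
``abnormal_low`` classification — a sustained reduction in the index.
Missing or non-analyzable days break the run.  With 4 learning days and a
3-day run the earliest possible alert is post-discharge day 7.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "DetectorConfig",
    "AlertSeries",
    "NORMAL",
    "ABNORMAL_LOW",
    "ABNORMAL_HIGH",
    "UNCLASSIFIED",
    "learn_baseline",
    "classify_day",
    "detect_alerts",
]

NORMAL = "normal"
ABNORMAL_LOW = "abnormal_low"
ABNORMAL_HIGH = "abnormal_high"
UNCLASSIFIED = "unclassified"

STATUS_OK = "ok"
STATUS_EXCLUDED = "excluded_no_learning_data"


@dataclass(frozen=True)
class DetectorConfig:
    learning_days: int = 4
    run_length: int = 3
    range_halfwidth_fraction: float = 0.10
    adaptation_rate: float = 0.1

    def __post_init__(self) -> None:
        bad = []
        if self.learning_days < 1:
            bad.append(f"learning_days must be >= 1 (got {self.learning_days})")
        if self.run_length < 1:
            bad.append(f"run_length must be >= 1 (got {self.run_length})")
        if not (0.0 < self.range_halfwidth_fraction < 1.0):
            bad.append(
                "range_halfwidth_fraction must be in (0, 1) "
                f"(got {self.range_halfwidth_fraction})"
            )
        if not (0.0 <= self.adaptation_rate < 1.0):
            bad.append(f"adaptation_rate must be in [0, 1) (got {self.adaptation_rate})")
        if bad:
            raise ValueError("; ".join(bad))

    @property
    def earliest_alert_day(self) -> int:
        return self.learning_days + self.run_length


@dataclass
class AlertSeries:
    """Per-day detector output for one patient.

    ``table`` has one row per day 1..monitoring_days: day, index_ohm (NaN if
    absent/non-analyzable), classification, alert (bool), expected_level,
    lower, upper (the band in effect when the day was classified; NaN during
    the learning period).  ``status`` is ``"excluded_no_learning_data"`` when
    no analyzable measurement fell in the learning period, in which case the
    table carries no classifications and no alerts.
    """

    patient_id: str
    status: str
    table: pd.DataFrame

    @property
    def excluded(self) -> bool:
        return self.status != STATUS_OK

    def alert_days(self) -> list[int]:
        t = self.table
        return [int(d) for d in t.loc[t["alert"], "day"]]


def learn_baseline(
    index_by_day: dict[int, float], config: DetectorConfig
) -> tuple[float, tuple[float, float]] | None:
    """Expected-normal level and range from the learning-period measurements.

    ``index_by_day`` maps day -> analyzable index.  Returns None when no
    analyzable measurement falls on days 1..learning_days (the patient is
    excluded from detection with an explicit status, never silently dropped).
    """
    values = [v for d, v in index_by_day.items() if 1 <= d <= config.learning_days]
    if not values:
        return None
    level = float(np.mean(values))
    h = config.range_halfwidth_fraction
    return level, (level * (1.0 - h), level * (1.0 + h))


def classify_day(index: float, lower: float, upper: float) -> str:
    """Classify one analyzable index value against the closed normal band."""
    if index < lower:
        return ABNORMAL_LOW
    if index > upper:
        return ABNORMAL_HIGH
    return NORMAL


def detect_alerts(
    index_by_day: dict[int, float],
    config: DetectorConfig,
    monitoring_days: int,
    patient_id: str = "",
) -> AlertSeries:
    """Run the adaptive detector over one patient's analyzable daily indices.

    ``index_by_day`` contains only analyzable measurements (day -> index in
    ohm); days absent from the mapping are treated as missing/non-analyzable.
    """
    learned = learn_baseline(index_by_day, config)
    days = np.arange(1, monitoring_days + 1)
    rows = {
        "day": days,
        "index_ohm": [index_by_day.get(int(d), np.nan) for d in days],
        "classification": [UNCLASSIFIED] * monitoring_days,
        "alert": [False] * monitoring_days,
        "expected_level": [np.nan] * monitoring_days,
        "lower": [np.nan] * monitoring_days,
        "upper": [np.nan] * monitoring_days,
    }
    if learned is None:
        return AlertSeries(
            patient_id=patient_id, status=STATUS_EXCLUDED, table=pd.DataFrame(rows)
        )

    level, _ = learned
    h = config.range_halfwidth_fraction
    a = config.adaptation_rate
    run = 0
    for i in range(config.learning_days, monitoring_days):
        day = i + 1
        lower, upper = level * (1.0 - h), level * (1.0 + h)
        value = index_by_day.get(day)
        if value is None:
            run = 0
            continue  # stays unclassified; band not recorded for absent days
        cls = classify_day(value, lower, upper)
        rows["classification"][i] = cls
        rows["expected_level"][i] = level
        rows["lower"][i] = lower
        rows["upper"][i] = upper
        if cls == ABNORMAL_LOW:
            run += 1
        else:
            run = 0
            if cls == NORMAL and a > 0.0:
                level = (1.0 - a) * level + a * value
        rows["alert"][i] = run >= config.run_length
    return AlertSeries(patient_id=patient_id, status=STATUS_OK, table=pd.DataFrame(rows))
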