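"""Measurement quality control and the usable-data inclusion rule.

A daily measurement is *analyzable* when its Cole fit converged and the RMS
spectrum residual is below a threshold; motion/contact artifacts inflate the
residual by an order of magnitude and are caught here.  A patient enters the
detection analysis only with sufficient usable data: at least 65% of the
scheduled monitoring days analyzable (with 45 scheduled days, >= 30 days).
Missing days (no record at all) count against the ratio.
"""

from __future__ import annotations

import math

import pandas as pd

__all__ = [
    "DEFAULT_RESIDUAL_THRESHOLD_OHM",
    "DEFAULT_SUFFICIENT_FRACTION",
    "classify_measurement",
    "sufficient_data",
    "min_analyzable_days",
    "adherence_table",
]

DEFAULT_RESIDUAL_THRESHOLD_OHM = 5.0
DEFAULT_SUFFICIENT_FRACTION = 0.65


def classify_measurement(
    fit_residual: float,
    converged: bool,
    residual_threshold: float = DEFAULT_RESIDUAL_THRESHOLD_OHM,
) -> bool:
    """True iff a present measurement is analyzable: converged fit and RMS
    residual at or below the threshold (ohm)."""
    return bool(converged) and fit_residual <= residual_threshold


def min_analyzable_days(
    monitoring_days: int, threshold_fraction: float = DEFAULT_SUFFICIENT_FRACTION
) -> int:
    """Smallest analyzable-day count whose ratio to scheduled days meets the
    inclusion fraction (30 for 45 days at 65%)."""
    return math.ceil(threshold_fraction * monitoring_days - 1e-9)


def sufficient_data(
    n_analyzable: int,
    monitoring_days: int,
    threshold_fraction: float = DEFAULT_SUFFICIENT_FRACTION,
) -> bool:
    """Inclusion rule: analyzable days / scheduled monitoring days >= fraction.

    The denominator is all scheduled days; an empty timeline simply fails the
    rule (it is not an error).
    """
    if monitoring_days <= 0:
        raise ValueError("monitoring_days must be positive")
    return n_analyzable / monitoring_days >= threshold_fraction


def adherence_table(
    index_df: pd.DataFrame,
    monitoring_days: int,
    residual_threshold: float = DEFAULT_RESIDUAL_THRESHOLD_OHM,
    threshold_fraction: float = DEFAULT_SUFFICIENT_FRACTION,
) -> pd.DataFrame:
    """Per-patient adherence summary from a fitted-index table.

    ``index_df`` needs columns patient_id, day, fit_residual_ohm, converged;
    one row per present measurement.  Returns one row per patient with
    n_analyzable, fraction and included (0/1).  The result is sorted by
    patient_id, so it does not depend on input row order.
    """
    df = index_df.copy()
    df["analyzable"] = [
        classify_measurement(r, bool(c), residual_threshold)
        for r, c in zip(df["fit_residual_ohm"], df["converged"])
    ]
    grouped = (
        df.groupby("patient_id", sort=True)["analyzable"].sum().astype(int).reset_index()
    )
    grouped = grouped.rename(columns={"analyzable": "n_analyzable"})
    grouped["fraction"] = grouped["n_analyzable"] / monitoring_days
    grouped["included"] = [
        int(sufficient_data(n, monitoring_days, threshold_fraction))
        for n in grouped["n_analyzable"]
    ]
    return grouped
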