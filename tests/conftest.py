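"""Shared fixtures and independent brute-force oracles.

The oracles re-derive detector alerts and day labels from the rule
definitions by explicit exhaustive loops (recomputing the adaptive level
from scratch for every day), independently of the package's incremental
implementations.
"""

from __future__ import annotations

import numpy as np
import pytest

from hfmonitor import ClinicalEvent, ColeParameters, ImpedanceSpectrum, cole_impedance
from hfmonitor.detect import DetectorConfig


@pytest.fixture
def freqs8() -> np.ndarray:
    return np.logspace(np.log10(5e3), 6, 8)


def make_spectrum(params: ColeParameters, freqs, noise_sd: float = 0.0, rng=None):
    z = np.asarray(cole_impedance(params, freqs))
    if noise_sd > 0:
        z = z + rng.normal(0, noise_sd, z.size) + 1j * rng.normal(0, noise_sd, z.size)
    return ImpedanceSpectrum(frequencies=np.asarray(freqs, float), impedances=z)


def oracle_detect_alerts(
    index_by_day: dict[int, float], cfg: DetectorConfig, monitoring_days: int
) -> list[int] | None:
    """Brute-force alert days: for every day, re-walk the whole history.

    Returns None when no analyzable learning-period measurement exists.
    """
    learn_vals = [index_by_day[d] for d in range(1, cfg.learning_days + 1) if d in index_by_day]
    if not learn_vals:
        return None
    h = cfg.range_halfwidth_fraction
    a = cfg.adaptation_rate

    def level_before(day: int) -> float:
        level = float(np.mean(learn_vals))
        for d in range(cfg.learning_days + 1, day):
            if d in index_by_day:
                v = index_by_day[d]
                if level * (1 - h) <= v <= level * (1 + h) and a > 0:
                    level = (1 - a) * level + a * v
        return level

    def is_low(day: int) -> bool:
        if day <= cfg.learning_days or day not in index_by_day:
            return False
        return index_by_day[day] < level_before(day) * (1 - h)

    alerts = []
    for d in range(1, monitoring_days + 1):
        if d >= cfg.learning_days + cfg.run_length and all(
            is_low(d - k) for k in range(cfg.run_length)
        ):
            alerts.append(d)
    return alerts


def oracle_label_days(
    alert_by_day: dict[int, bool],
    events: list[ClinicalEvent],
    detection_window: int,
    critical_window: int,
    evaluable_days,
) -> dict[int, str]:
    """Brute-force day labels: explicit loop over all events per day."""
    labels = {}
    for day in evaluable_days:
        in_det = False
        in_crit = False
        for e in events:
            if e.day - detection_window <= day <= e.day - 1:
                in_det = True
            if e.day - critical_window <= day <= e.day - 1:
                in_crit = True
        if alert_by_day.get(day, False):
            labels[day] = "TP" if in_det else "FP"
        else:
            labels[day] = "FN" if in_crit else "TN"
    return labels


def random_index_timeline(rng: np.random.Generator, monitoring_days: int = 45):
    """Random analyzable-index mapping stressing run/reset edge cases."""
    baseline = rng.uniform(300, 700)
    index_by_day = {}
    for day in range(1, monitoring_days + 1):
        if rng.random() < 0.25:  # missing / non-analyzable
            continue
        # values straddle the +-10% band edges to exercise boundary behavior
        index_by_day[day] = baseline * rng.uniform(0.75, 1.25)
    return index_by_day


def random_events(rng: np.random.Generator, surveillance_days: int = 75):
    n = rng.integers(0, 4)
    days = sorted(rng.choice(np.arange(1, surveillance_days + 1), size=n, replace=False))
    types = ["readmission", "diuretic_uptitration"]
    return [ClinicalEvent(day=int(d), type=types[int(rng.integers(0, 2))]) for d in days]
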