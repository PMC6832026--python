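"""Day-level labeling, pooled performance, lead times and the window grid."""

import numpy as np
import pandas as pd
import pytest

from hfmonitor import (
    ClinicalEvent,
    ConfusionCounts,
    WindowConfig,
    composite_event_counts,
    cluster_bootstrap_ci,
    label_days,
    lead_times,
    performance,
    pool_counts,
    sensitivity_grid,
)
from tests.conftest import oracle_label_days, random_events

EVAL_DAYS = range(7, 46)


def up(day):
    return ClinicalEvent(day=day, type="diuretic_uptitration")


class TestLabelDays:
    def test_alert_inside_detection_window_is_tp(self):
        t = label_days({20: True}, [up(35)], WindowConfig(), EVAL_DAYS)
        assert t.set_index("day").loc[20, "label"] == "TP"

    def test_alert_without_event_is_fp(self):
        t = label_days({20: True}, [], WindowConfig(), EVAL_DAYS)
        assert t.set_index("day").loc[20, "label"] == "FP"

    def test_silent_day_in_critical_window_is_fn(self):
        t = label_days({}, [up(35)], WindowConfig(critical_window=3), EVAL_DAYS)
        by_day = t.set_index("day")["label"]
        assert by_day.loc[33] == "FN"
        assert (by_day.loc[[32, 33, 34]] == "FN").all()
        assert by_day.loc[31] == "TN"  # just outside the critical window

    def test_event_day_itself_not_pre_event(self):
        t = label_days({}, [up(35)], WindowConfig(), EVAL_DAYS)
        assert t.set_index("day").loc[35, "label"] == "TN"

    def test_no_alerts_no_events_all_tn(self):
        t = label_days({}, [], WindowConfig(), EVAL_DAYS)
        assert (t["label"] == "TN").all()
        assert len(t) == len(list(EVAL_DAYS))

    def test_invalid_windows_rejected(self):
        with pytest.raises(ValueError):
            WindowConfig(detection_window=14, critical_window=20)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(300):
            events = random_events(rng)
            alert_by_day = {int(d): True for d in rng.choice(45, rng.integers(0, 15)) + 1}
            d_width = int(rng.choice([14, 21, 30]))
            w_width = int(rng.choice([3, 7, 14]))
            windows = WindowConfig(d_width, w_width)
            t = label_days(alert_by_day, events, windows, EVAL_DAYS)
            expected = oracle_label_days(alert_by_day, events, d_width, w_width, EVAL_DAYS)
            assert dict(zip(t["day"], t["label"])) == expected

    def test_conservation(self):
        rng = np.random.default_rng(6)
        for _ in range(50):
            events = random_events(rng)
            alerts = {int(d): True for d in rng.choice(45, 5) + 1}
            t = label_days(alerts, events, WindowConfig(), EVAL_DAYS)
            counts = ConfusionCounts.from_labels(t["label"])
            assert counts.total == len(list(EVAL_DAYS))


class TestPoolAndPerformance:
    def test_pooling_is_elementwise_addition(self):
        a = ConfusionCounts(2, 1, 30, 0)
        b = ConfusionCounts(0, 3, 28, 2)
        assert a + b == ConfusionCounts(2, 4, 58, 2)
        assert pool_counts([]) == ConfusionCounts()

    def test_rates_arithmetic(self):
        perf = performance(ConfusionCounts(tp=87, fn=13, tn=700, fp=300))
        assert perf.sensitivity == pytest.approx(0.87)
        assert perf.specificity == pytest.approx(0.70)
        assert perf.accuracy == pytest.approx(0.7155, abs=1e-4)
        lo, hi = perf.sensitivity_ci
        assert lo < 0.87 < hi

    def test_undefined_rates_are_explicit_markers(self):
        perf = performance(ConfusionCounts(tp=0, fn=0, tn=10, fp=5))
        assert perf.sensitivity is None and perf.sensitivity_ci is None
        assert perf.specificity is not None

    def test_perfect_detector(self):
        perf = performance(ConfusionCounts(tp=9, fn=0, tn=30, fp=0))
        assert (perf.sensitivity, perf.specificity, perf.accuracy) == (1.0, 1.0, 1.0)

    def test_cluster_bootstrap_brackets_point_estimate(self):
        rng = np.random.default_rng(7)
        tables = []
        for _ in range(30):
            labels = rng.choice(["TP", "FN"], size=20, p=[0.8, 0.2])
            tables.append(pd.DataFrame({"day": range(20), "alert": True, "label": labels}))
        lo, hi = cluster_bootstrap_ci(tables, "sensitivity", n_boot=200, seed=1)
        pooled = performance(pool_counts(tables)).sensitivity
        assert lo <= pooled <= hi


class TestLeadTimes:
    def test_first_in_window_alert(self):
        mean, median, leads = lead_times(
            [({20: True, 21: True, 22: True}, [up(35)])], WindowConfig()
        )
        assert leads == [15] and mean == 15 and median == 15

    def test_alert_on_event_eve(self):
        _, _, leads = lead_times([({34: True}, [up(35)])], WindowConfig())
        assert leads == [1]

    def test_two_events_sharing_one_alert_run(self):
        alerts = {d: True for d in (20, 21, 22)}
        _, _, leads = lead_times([(alerts, [up(30), up(40)])], WindowConfig())
        # each event takes its own first in-window alert day (both see day 20)
        assert leads == [10, 20]

    def test_no_alerted_events_empty_marker(self):
        assert lead_times([({}, [up(35)])], WindowConfig()) == (None, None, [])


@pytest.fixture(scope="module")
def cohort():
    rng = np.random.default_rng(8)
    per_patient = []
    for _ in range(40):
        events = random_events(rng)
        alerts = {int(d): True for d in rng.choice(45, rng.integers(0, 12)) + 1}
        per_patient.append((alerts, events))
    return per_patient


class TestSensitivityGrid:
    def test_grid_shape_and_counts(self, cohort):
        grid = sensitivity_grid(cohort, EVAL_DAYS)
        assert len(grid) == 9
        assert set(grid["detection_window"]) == {14, 21, 30}
        assert (grid["n_subjects"] == 40).all()
        assert (grid["tp"] + grid["fp"] + grid["tn"] + grid["fn"]
                == 40 * len(list(EVAL_DAYS))).all()

    def test_sensitivity_nonincreasing_in_critical_window(self, cohort):
        grid = sensitivity_grid(cohort, EVAL_DAYS).set_index(
            ["detection_window", "critical_window"]
        )
        for d in (14, 21, 30):
            sens = [grid.loc[(d, w), "sensitivity"] for w in (3, 7, 14)]
            assert all(a >= b - 1e-12 for a, b in zip(sens, sens[1:]))

    def test_specificity_and_sensitivity_nondecreasing_in_detection_window(self, cohort):
        grid = sensitivity_grid(cohort, EVAL_DAYS).set_index(
            ["detection_window", "critical_window"]
        )
        for w in (3, 7, 14):
            spec = [grid.loc[(d, w), "specificity"] for d in (14, 21, 30)]
            sens = [grid.loc[(d, w), "sensitivity"] for d in (14, 21, 30)]
            assert all(a <= b + 1e-12 for a, b in zip(spec, spec[1:]))
            assert all(a <= b + 1e-12 for a, b in zip(sens, sens[1:]))

    def test_subjects_with_events_can_grow_with_detection_window(self, cohort):
        # a late event's window reaches back into the evaluable range only
        # for large D, so the evaluable-subject count is non-decreasing in D
        grid = sensitivity_grid(cohort, EVAL_DAYS).set_index(
            ["detection_window", "critical_window"]
        )
        for w in (3, 7, 14):
            ns = [grid.loc[(d, w), "n_subjects_with_events"] for d in (14, 21, 30)]
            assert ns == sorted(ns)


class TestCompositeEndpoint:
    def test_counts_sum_by_arm(self):
        df = pd.DataFrame(
            {
                "patient_id": ["A", "A", "B", "C"],
                "day": [10, 40, 20, 30],
                "type": ["readmission", "diuretic_uptitration",
                         "diuretic_uptitration", "diuretic_uptitration"],
            }
        )
        counts = composite_event_counts(df)
        assert counts == {
            "n_readmission": 1,
            "n_uptitration": 3,
            "n_composite": 4,
            "n_patients_with_events": 3,
        }
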