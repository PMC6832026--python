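"""Run configuration, CSV/JSON I/O and the end-to-end analysis pipeline.

The pipeline chains the stages the way the study analysis ran them:

    simulate -> fit Cole spectra -> QC / inclusion -> adaptive alert
    detection -> day-level evaluation (+ window sensitivity grid)

Every stage persists its inputs and outputs as plain CSV/JSON so stages are
individually re-runnable from files, and a manifest records the seed and a
hash of the configuration.  All file formats are UTF-8 CSV with a header
row and integer day columns.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import detect, evaluate, qc
from .cole import ImpedanceSpectrum, bioimpedance_index, fit_cole
from .simulate import (
    CohortConfig,
    ConfigurationError,
    PatientTimeline,
    simulate_cohort,
)

__all__ = [
    "RunConfig",
    "run_pipeline",
    "write_spectra_csv",
    "read_spectra_csv",
    "write_events_csv",
    "read_events_csv",
    "write_truth_csv",
    "fit_spectra",
    "read_csv_checked",
    "alerts_long_table",
]

logger = logging.getLogger("hfmonitor")

SPECTRA_COLUMNS = ["patient_id", "day", "frequency_hz", "z_real_ohm", "z_imag_ohm"]
EVENTS_COLUMNS = ["patient_id", "day", "type"]
INDEX_COLUMNS = ["patient_id", "day", "index_ohm", "fit_residual_ohm", "converged"]


@dataclass(frozen=True)
class RunConfig:
    """Everything one reproducible run needs: cohort, detector, windows, QC."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    detector: detect.DetectorConfig = field(default_factory=detect.DetectorConfig)
    windows: evaluate.WindowConfig = field(default_factory=evaluate.WindowConfig)
    residual_threshold_ohm: float = qc.DEFAULT_RESIDUAL_THRESHOLD_OHM
    sufficient_fraction: float = qc.DEFAULT_SUFFICIENT_FRACTION
    include_warmup_days: bool = False  # label never-alertable days 1..6 as TN

    def validate(self) -> None:
        self.cohort.validate()
        bad = []
        if self.detector.earliest_alert_day > self.cohort.monitoring_days:
            bad.append(
                "learning_days + run_length must not exceed monitoring_days "
                f"({self.detector.earliest_alert_day} > {self.cohort.monitoring_days})"
            )
        if not (0 < self.sufficient_fraction <= 1):
            bad.append(f"sufficient_fraction must be in (0, 1] (got {self.sufficient_fraction})")
        if self.residual_threshold_ohm <= 0:
            bad.append(f"residual_threshold_ohm must be > 0 (got {self.residual_threshold_ohm})")
        if bad:
            raise ConfigurationError("; ".join(bad))
        # WindowConfig and DetectorConfig already validate themselves on construction

    def evaluable_days(self) -> range:
        start = 1 if self.include_warmup_days else self.detector.earliest_alert_day
        return range(start, self.cohort.monitoring_days + 1)

    # ---- JSON round trip ---------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "cohort": dataclasses.asdict(self.cohort),
            "detector": dataclasses.asdict(self.detector),
            "windows": dataclasses.asdict(self.windows),
            "residual_threshold_ohm": self.residual_threshold_ohm,
            "sufficient_fraction": self.sufficient_fraction,
            "include_warmup_days": self.include_warmup_days,
        }

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        kwargs = dict(data)
        if "cohort" in kwargs:
            kwargs["cohort"] = CohortConfig(**kwargs["cohort"])
        if "detector" in kwargs:
            kwargs["detector"] = detect.DetectorConfig(**kwargs["detector"])
        if "windows" in kwargs:
            kwargs["windows"] = evaluate.WindowConfig(**kwargs["windows"])
        return cls(**kwargs)

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(json.load(fh))

    def config_hash(self) -> str:
        canon = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


# ---- CSV schemas ------------------------------------------------------------


def read_csv_checked(path: str | Path, required: list[str]) -> pd.DataFrame:
    """Read a CSV and verify required columns, naming any missing one."""
    df = pd.read_csv(path)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    return df


def write_spectra_csv(cohort: list[PatientTimeline], path: str | Path) -> None:
    rows = []
    for pt in cohort:
        for m in pt.measurements:
            for f, z in zip(m.spectrum.frequencies, m.spectrum.impedances):
                rows.append((pt.patient_id, m.day, f, z.real, z.imag))
    pd.DataFrame(rows, columns=SPECTRA_COLUMNS).to_csv(path, index=False)


def read_spectra_csv(path: str | Path) -> pd.DataFrame:
    df = read_csv_checked(path, SPECTRA_COLUMNS)
    df["day"] = df["day"].astype(int)
    return df


def write_events_csv(cohort: list[PatientTimeline], path: str | Path) -> None:
    rows = [(pt.patient_id, e.day, e.type) for pt in cohort for e in pt.events]
    pd.DataFrame(rows, columns=EVENTS_COLUMNS).to_csv(path, index=False)


def read_events_csv(path: str | Path) -> pd.DataFrame:
    df = read_csv_checked(path, EVENTS_COLUMNS)
    df["day"] = df["day"].astype(int)
    return df


def write_truth_csv(cohort: list[PatientTimeline], path: str | Path) -> None:
    """Latent noise-free index per day — test-only ground truth."""
    rows = []
    for pt in cohort:
        present = {m.day: m for m in pt.measurements}
        for i, latent in enumerate(pt.truth_latent_index):
            day = i + 1
            m = present.get(day)
            rows.append(
                (
                    pt.patient_id,
                    day,
                    latent,
                    m.truth_observed_index if m else np.nan,
                    int(m is None),
                    int(m.truth_nonanalyzable) if m else 0,
                )
            )
    pd.DataFrame(
        rows,
        columns=[
            "patient_id",
            "day",
            "latent_index_ohm",
            "observed_index_ohm",
            "missing",
            "nonanalyzable_truth",
        ],
    ).to_csv(path, index=False)


# ---- stages -----------------------------------------------------------------


def fit_spectra(spectra_df: pd.DataFrame) -> pd.DataFrame:
    """Fit every (patient, day) spectrum; one fitted-index row per measurement."""
    rows = []
    for (pid, day), grp in spectra_df.groupby(["patient_id", "day"], sort=True):
        grp = grp.sort_values("frequency_hz")
        spectrum = ImpedanceSpectrum(
            frequencies=grp["frequency_hz"].to_numpy(),
            impedances=grp["z_real_ohm"].to_numpy() + 1j * grp["z_imag_ohm"].to_numpy(),
        )
        fit = fit_cole(spectrum)
        rows.append(
            (
                pid,
                int(day),
                bioimpedance_index(fit.params),
                fit.residual_rms,
                int(fit.converged and not fit.degenerate),
            )
        )
    return pd.DataFrame(rows, columns=INDEX_COLUMNS)


def _analyzable_index_maps(
    index_df: pd.DataFrame, residual_threshold: float
) -> dict[str, dict[int, float]]:
    out: dict[str, dict[int, float]] = {}
    for pid, grp in index_df.groupby("patient_id", sort=True):
        m = {}
        for _, row in grp.iterrows():
            if qc.classify_measurement(
                row["fit_residual_ohm"], bool(row["converged"]), residual_threshold
            ):
                m[int(row["day"])] = float(row["index_ohm"])
        out[pid] = m
    return out


def alerts_long_table(series_list: list[detect.AlertSeries]) -> pd.DataFrame:
    """Stack per-patient alert series into one long table for the alerts CSV."""
    frames = []
    for s in series_list:
        t = s.table.copy()
        t.insert(0, "patient_id", s.patient_id)
        t["alert"] = t["alert"].astype(int)
        frames.append(t)
    if not frames:
        return pd.DataFrame(
            columns=["patient_id", "day", "index_ohm", "classification", "alert",
                     "expected_level", "lower", "upper"]
        )
    return pd.concat(frames, ignore_index=True)


def run_pipeline(config: RunConfig, out_dir: str | Path) -> dict:
    """Execute every stage, persisting all artifacts under ``out_dir``.

    Deterministic given ``config`` (which carries the seed).  Returns a
    summary dict mirroring the performance JSON written to disk.
    """
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    def stage(name):
        logger.info("stage: %s", name)

    stage("simulate")
    cohort = simulate_cohort(config.cohort)
    write_spectra_csv(cohort, out / "spectra.csv")
    write_events_csv(cohort, out / "events.csv")
    write_truth_csv(cohort, out / "truth.csv")

    stage("fit")
    index_df = fit_spectra(read_spectra_csv(out / "spectra.csv"))
    index_df.to_csv(out / "fitted_index.csv", index=False)

    stage("qc")
    adherence = qc.adherence_table(
        index_df,
        config.cohort.monitoring_days,
        config.residual_threshold_ohm,
        config.sufficient_fraction,
    )
    adherence.to_csv(out / "adherence.csv", index=False)
    included_ids = set(adherence.loc[adherence["included"] == 1, "patient_id"])

    stage("detect")
    index_maps = _analyzable_index_maps(index_df, config.residual_threshold_ohm)
    events_by_pid = {pt.patient_id: pt.events for pt in cohort}
    series_list = []
    excluded_no_baseline = []
    for pid in sorted(included_ids):
        series = detect.detect_alerts(
            index_maps.get(pid, {}), config.detector, config.cohort.monitoring_days, pid
        )
        if series.excluded:
            excluded_no_baseline.append(pid)
            logger.info("patient %s excluded from detection: %s", pid, series.status)
        else:
            series_list.append(series)
    alerts_long_table(series_list).to_csv(out / "alerts.csv", index=False)

    stage("evaluate")
    evaluable = list(config.evaluable_days())
    per_patient = []
    tables = []
    for s in series_list:
        alert_by_day = {int(r.day): bool(r.alert) for r in s.table.itertuples()}
        events = events_by_pid.get(s.patient_id, [])
        per_patient.append((alert_by_day, events))
        tables.append(evaluate.label_days(alert_by_day, events, config.windows, evaluable))
    label_df = pd.concat(
        [t.assign(patient_id=s.patient_id) for s, t in zip(series_list, tables)],
        ignore_index=True,
    ) if tables else pd.DataFrame(columns=["day", "alert", "label", "patient_id"])
    label_df.to_csv(out / "day_labels.csv", index=False)

    counts = evaluate.pool_counts(tables)
    perf = evaluate.performance(counts)
    mean_lead, median_lead, leads = evaluate.lead_times(per_patient, config.windows)
    n_with_events = sum(
        1
        for _, events in per_patient
        if evaluate._evaluable_events(events, evaluable, config.windows.detection_window)
    ) if per_patient else 0

    summary = {
        "n_patients_simulated": config.cohort.n_patients,
        "n_patients_included": len(included_ids),
        "n_patients_detected": len(series_list),
        "n_patients_excluded_no_baseline": len(excluded_no_baseline),
        "n_subjects_with_evaluable_events": n_with_events,
        "counts": dataclasses.asdict(counts),
        "sensitivity": perf.sensitivity,
        "specificity": perf.specificity,
        "accuracy": perf.accuracy,
        "sensitivity_ci": perf.sensitivity_ci,
        "specificity_ci": perf.specificity_ci,
        "accuracy_ci": perf.accuracy_ci,
        "mean_lead_days": mean_lead,
        "median_lead_days": median_lead,
        "n_alerted_events": len(leads),
        "endpoints": evaluate.composite_event_counts(read_events_csv(out / "events.csv"))
        if (out / "events.csv").exists()
        else None,
    }
    with open(out / "performance.json", "w", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=2)

    stage("grid")
    grid = evaluate.sensitivity_grid(per_patient, evaluable)
    grid.to_csv(out / "grid.csv", index=False)

    manifest = {"seed": config.cohort.seed, "config_hash": config.config_hash(),
                "config": config.to_dict()}
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2)
    return summary
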