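"""Seeded synthetic post-discharge cohort with daily bioimpedance timelines.

Emulates the data structure of a home-telemonitoring study of patients
discharged after acute decompensated heart failure: each patient performs
daily multifrequency thoracic-bioimpedance measurements for a 45-day
monitoring period, while clinical heart-failure events (readmission or
diuretic uptitration) are surveilled for 75 days.

The latent daily index trajectory per patient is a flat patient-specific
baseline (drawn across patients from a normal distribution) perturbed by
mean-one lognormal day-to-day noise.  Decompensation episodes depress it: the
index declines linearly over ``decline_lead_days`` to
``baseline * (1 - decline_fraction)`` at the event day, then recovers
linearly to baseline over ``recovery_days`` (treatment — in-hospital for a
readmission, dose increase for an uptitration — ends the fluid accumulation).
Events arise from a constant per-day hazard with a refractory period of one
decline lead after each event.  Measurements can be missing (no record) or
present but artifact-corrupted (non-analyzable); artifacts are injected as
large-amplitude spectrum noise plus an explicit truth flag so the
quality-control classifier has a real signal to detect.

All randomness flows from a single cohort seed: patient ``i`` uses
``numpy.random.SeedSequence(entropy=[cohort_seed, i])``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .cole import ColeParameters, ImpedanceSpectrum, cole_impedance

__all__ = [
    "CohortConfig",
    "ClinicalEvent",
    "SpectrumMeasurement",
    "PatientTimeline",
    "ConfigurationError",
    "simulate_cohort",
    "simulate_patient",
    "expected_events_per_patient",
]

READMISSION = "readmission"
UPTITRATION = "diuretic_uptitration"
EVENT_TYPES = (READMISSION, UPTITRATION)


class ConfigurationError(ValueError):
    """Invalid cohort configuration; message lists every violated field."""


@dataclass(frozen=True)
class CohortConfig:
    """Study-design and noise parameters of the synthetic cohort.

    Defaults emulate the published study design: 45 scheduled daily
    measurements, 75 days of event surveillance, ~0.6 events per patient
    (constant hazard 0.008/day) of which ~28% are readmissions.
    """

    n_patients: int = 50
    monitoring_days: int = 45
    surveillance_days: int = 75
    seed: int = 0
    baseline_mean: float = 500.0
    baseline_between_patient_sd: float = 50.0
    daily_cv: float = 0.02
    event_hazard: float = 0.008
    p_readmission: float = 0.28
    decline_lead_days: int = 14
    decline_fraction: float = 0.25
    recovery_days: int = 7
    p_missing_day: float = 0.10
    p_nonanalyzable: float = 0.05
    spectrum_noise_sd: float = 1.0
    # measurement-layer constants (Cole spectrum synthesis)
    n_frequencies: int = 8
    f_min_hz: float = 5e3
    f_max_hz: float = 1e6
    r_inf_ratio: float = 0.6
    f_c_hz: float = 50e3
    cole_alpha: float = 0.8
    artifact_noise_multiplier: float = 20.0

    def validate(self) -> None:
        bad = []
        for name in ("p_readmission", "p_missing_day", "p_nonanalyzable", "event_hazard"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                bad.append(f"{name} must be in [0, 1] (got {v})")
        if not (0.0 < self.decline_fraction < 1.0):
            bad.append(f"decline_fraction must be in (0, 1) (got {self.decline_fraction})")
        if self.monitoring_days > self.surveillance_days:
            bad.append(
                f"monitoring_days ({self.monitoring_days}) must not exceed "
                f"surveillance_days ({self.surveillance_days})"
            )
        if self.decline_lead_days < 1:
            bad.append(f"decline_lead_days must be >= 1 (got {self.decline_lead_days})")
        if self.n_patients < 1:
            bad.append(f"n_patients must be >= 1 (got {self.n_patients})")
        if self.recovery_days < 1:
            bad.append(f"recovery_days must be >= 1 (got {self.recovery_days})")
        if self.daily_cv < 0:
            bad.append(f"daily_cv must be >= 0 (got {self.daily_cv})")
        if self.baseline_mean <= 0:
            bad.append(f"baseline_mean must be > 0 (got {self.baseline_mean})")
        if not (0 < self.r_inf_ratio < 1):
            bad.append(f"r_inf_ratio must be in (0, 1) (got {self.r_inf_ratio})")
        if bad:
            raise ConfigurationError("; ".join(bad))

    def frequencies(self) -> np.ndarray:
        return np.logspace(
            math.log10(self.f_min_hz), math.log10(self.f_max_hz), self.n_frequencies
        )


@dataclass(frozen=True)
class ClinicalEvent:
    """One adjudicated heart-failure event on a 1-based post-discharge day."""

    day: int
    type: str

    def __post_init__(self) -> None:
        if self.day < 1:
            raise ValueError(f"event day must be >= 1 (got {self.day})")
        if self.type not in EVENT_TYPES:
            raise ValueError(f"event type must be one of {EVENT_TYPES} (got {self.type!r})")


@dataclass(frozen=True)
class SpectrumMeasurement:
    """One present daily measurement: the raw spectrum plus truth flags."""

    day: int
    spectrum: ImpedanceSpectrum
    truth_nonanalyzable: bool
    truth_observed_index: float


@dataclass
class PatientTimeline:
    """All simulated data for one patient.

    ``truth_latent_index`` holds the noise-free latent index for days
    1..monitoring_days and exists for testing only; real studies never
    observe it.
    """

    patient_id: str
    measurements: list[SpectrumMeasurement]
    events: list[ClinicalEvent]
    truth_latent_index: np.ndarray = field(repr=False)

    def measurement_days(self) -> list[int]:
        return [m.day for m in self.measurements]


def _patient_rng(seed: int, patient_index: int) -> np.random.Generator:
    """Splitting rule: patient i draws from SeedSequence([cohort_seed, i])."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), int(patient_index)]))


def _draw_events(cfg: CohortConfig, rng: np.random.Generator) -> list[ClinicalEvent]:
    events: list[ClinicalEvent] = []
    refractory_until = 0
    for day in range(1, cfg.surveillance_days + 1):
        hit = rng.random() < cfg.event_hazard
        if day <= refractory_until:
            continue
        if hit:
            etype = READMISSION if rng.random() < cfg.p_readmission else UPTITRATION
            events.append(ClinicalEvent(day=day, type=etype))
            refractory_until = day + cfg.decline_lead_days
    return events


def _episode_drop(day: int, event_day: int, cfg: CohortConfig) -> float:
    """Fractional index depression contributed by one event at a given day."""
    lead, rec, frac = cfg.decline_lead_days, cfg.recovery_days, cfg.decline_fraction
    if event_day - lead <= day <= event_day:
        return frac * (1.0 - (event_day - day) / lead)
    if event_day < day <= event_day + rec:
        return frac * (1.0 - (day - event_day) / rec)
    return 0.0


def _latent_trajectory(
    baseline: float, events: list[ClinicalEvent], cfg: CohortConfig
) -> np.ndarray:
    days = np.arange(1, cfg.monitoring_days + 1)
    latent = np.empty(days.size)
    for i, d in enumerate(days):
        drop = max((_episode_drop(int(d), e.day, cfg) for e in events), default=0.0)
        latent[i] = baseline * (1.0 - drop)
    return latent


def _synthesize_spectrum(
    cfg: CohortConfig,
    observed_index: float,
    artifact: bool,
    rng: np.random.Generator,
) -> ImpedanceSpectrum:
    params = ColeParameters(
        r_zero=observed_index,
        r_inf=cfg.r_inf_ratio * observed_index,
        f_c=cfg.f_c_hz,
        alpha=cfg.cole_alpha,
    )
    freqs = cfg.frequencies()
    z = np.asarray(cole_impedance(params, freqs))
    sd = cfg.spectrum_noise_sd * (cfg.artifact_noise_multiplier if artifact else 1.0)
    if sd > 0:
        z = z + rng.normal(0.0, sd, z.size) + 1j * rng.normal(0.0, sd, z.size)
    return ImpedanceSpectrum(frequencies=freqs, impedances=z)


def simulate_patient(cfg: CohortConfig, patient_index: int) -> PatientTimeline:
    """Simulate one patient, reproducibly, from the cohort seed and index."""
    rng = _patient_rng(cfg.seed, patient_index)
    baseline = max(rng.normal(cfg.baseline_mean, cfg.baseline_between_patient_sd), 1.0)
    events = _draw_events(cfg, rng)
    latent = _latent_trajectory(baseline, events, cfg)

    # mean-one lognormal multipliers with the requested coefficient of variation
    if cfg.daily_cv > 0:
        sigma = math.sqrt(math.log(1.0 + cfg.daily_cv**2))
        noise = np.exp(rng.normal(-0.5 * sigma**2, sigma, cfg.monitoring_days))
    else:
        noise = np.ones(cfg.monitoring_days)

    missing = rng.random(cfg.monitoring_days) < cfg.p_missing_day
    artifact = rng.random(cfg.monitoring_days) < cfg.p_nonanalyzable

    measurements = []
    for i in range(cfg.monitoring_days):
        if missing[i]:
            continue
        observed = float(latent[i] * noise[i])
        spec = _synthesize_spectrum(cfg, observed, bool(artifact[i]), rng)
        measurements.append(
            SpectrumMeasurement(
                day=i + 1,
                spectrum=spec,
                truth_nonanalyzable=bool(artifact[i]),
                truth_observed_index=observed,
            )
        )
    return PatientTimeline(
        patient_id=f"P{patient_index:04d}",
        measurements=measurements,
        events=events,
        truth_latent_index=latent,
    )


def simulate_cohort(cfg: CohortConfig) -> list[PatientTimeline]:
    """Simulate the full cohort; identical config and seed give identical data."""
    cfg.validate()
    return [simulate_patient(cfg, i) for i in range(cfg.n_patients)]


def expected_events_per_patient(cfg: CohortConfig) -> float:
    """Exact expected event count per patient under the hazard-with-refractory
    process, by dynamic programming over (day, days-left-in-refractory).

    Serves as an independent closed-form oracle for the event generator: a
    Bernoulli(hazard) draw is made every day, but a success only registers as
    an event when the refractory counter from the previous event has expired.
    """
    h = cfg.event_hazard
    r = cfg.decline_lead_days
    # state: probability distribution over days remaining in refractory (0..r)
    p_state = np.zeros(r + 1)
    p_state[0] = 1.0
    expected = 0.0
    for _day in range(1, cfg.surveillance_days + 1):
        p_free = p_state[0]
        expected += p_free * h
        new_state = np.zeros(r + 1)
        # free and event -> enter refractory for r days (next event allowed day+r+1)
        new_state[r] += p_free * h
        new_state[0] += p_free * (1.0 - h)
        new_state[: r] += p_state[1:]
        p_state = new_state
    return expected
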