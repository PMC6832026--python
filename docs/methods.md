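# Methods

## Problem and scope

`hfmonitor` implements a complete, testable version of a daily
thoracic-bioimpedance telemonitoring analysis for patients discharged after
acute decompensated heart failure (ADHF). Thoracic bioimpedance falls as
intrathoracic fluid accumulates, so a sustained decline in a daily
bioimpedance index can precede a clinical heart-failure (HF) event —
an unplanned HF readmission or a diuretic uptitration — by days to weeks.
The package covers the computational chain only: measurement model, daily
index extraction, quality control and cohort inclusion, patient-adaptive
alerting, and day-level performance evaluation. Recruitment, adjudication
workflow, instruments (KCCQ/TICS) and device/app infrastructure are out of
scope.

Because no real patient data are public, the package ships a synthetic
cohort generator that reproduces the *structure* of such a study — 45
scheduled daily measurements, 75 days of event surveillance, missingness,
artifacts, pre-event index declines — so every downstream stage is exercised
end to end.

## Measurement model and daily index

Each daily measurement is a multifrequency impedance spectrum modeled by the
single-dispersion Cole–Cole relaxation

    Z(f) = R_inf + (R_0 − R_inf) / (1 + (j f / f_c)^alpha),

with R_0 > R_inf > 0 (ohm), characteristic frequency f_c > 0 (Hz) and
dispersion exponent alpha in (0, 1]. Spectra are fit by box-constrained
nonlinear least squares on the stacked real/imaginary residuals
(`scipy.optimize.least_squares`, trust-region reflective, analytic
Jacobian). The fit is parametrized as (R_inf, ΔR = R_0 − R_inf, ln f_c,
alpha) so the ordering constraint R_0 > R_inf reduces to positivity of ΔR;
bounds are R_inf, ΔR > 0, f_c in [1 Hz, 1 GHz] (on the log scale) and alpha
in [0.3, 1]. Initialization: R_0 = max |Z|, R_inf = min |Z|, f_c at the
frequency of the most negative reactance, alpha = 0.8; cost tolerance 1e-10.
Non-convergence and degeneracy (fitted dispersion ΔR below 0.1% of R_0, as
for a flat spectrum) are *flags* carried into quality control, never
exceptions.

The daily **bioimpedance index** is the fitted R_0. Rationale:
extracellular fluid — the compartment that expands in congestion — governs
low-frequency resistance, so R_0 is the parameter most directly sensitive to
thoracic fluid. This is a package design choice (the field uses several
summaries); it is isolated behind `bioimpedance_index` so an alternative
(e.g. |Z| at a fixed frequency) can be substituted without touching the
detector. Default simulated frequencies: 8 log-spaced points in
[5 kHz, 1 MHz], the usual bioimpedance-spectroscopy band.

## Synthetic cohort generator

Per patient (all parameters are `CohortConfig` fields; units in brackets):

* baseline index ~ Normal(`baseline_mean` = 500 Ω, `baseline_between_patient_sd`
  = 50 Ω), truncated at 1 Ω;
* events: per-day Bernoulli hazard `event_hazard` = 0.008 over
  `surveillance_days` = 75, with a refractory period of one decline lead
  after each event; each event is a readmission with probability
  `p_readmission` = 0.28, else a diuretic uptitration. The hazard and arm
  split are matched to the full-cohort rates of the motivating study design
  (~0.6 events/patient over 75 days, ~28% readmissions); a constant hazard
  matches events being spread evenly across follow-up;
* latent trajectory: flat at baseline except during episodes, where the
  index declines **linearly** to `baseline · (1 − decline_fraction)` over
  `decline_lead_days` ending at the event day, then recovers linearly over
  `recovery_days` (readmissions also end the decline — the patient is
  treated in hospital). Overlapping episodes take the deeper depression.
  Defaults: decline 25% over 14 days, recovery 7 days. No published value
  exists for the decline magnitude or lead; these are free parameters chosen
  once as a plausible congestion build-up (see "Detectability" below);
* daily observation: latent value × mean-one lognormal noise with
  coefficient of variation `daily_cv` = 0.02;
* missingness: each day absent with `p_missing_day` = 0.10; each present
  measurement artifact-corrupted with `p_nonanalyzable` = 0.05, implemented
  as 20× (`artifact_noise_multiplier`) the nominal spectrum noise
  (`spectrum_noise_sd` = 1 Ω per real/imaginary component) plus a truth
  flag;
* spectrum synthesis: Cole model with R_0 = observed index,
  R_inf = 0.6 · R_0, f_c = 50 kHz, alpha = 0.8.

Randomness: patient *i* draws from
`numpy.random.SeedSequence([cohort_seed, i])`, so cohorts are reproducible
and patients independent.

What the generator does **not** emulate: covariates and their association
with risk, the staff-escalation/withdrawal ladder (only a flat missingness
rate), within-patient autocorrelated noise, circadian/posture effects,
electrode-contact drift, or informative missingness around events. Passing
tests therefore demonstrate the pipeline's correctness and its behavior
under the stated statistical structure — not clinical performance on real
patients.

## Quality control and inclusion

A measurement is **analyzable** iff its Cole fit converged, is
non-degenerate, and the RMS residual is ≤ `residual_threshold_ohm` = 5 Ω.
The threshold separates the nominal 1 Ω noise floor (fit residual ≈ 1 Ω)
from 20 Ω artifact noise by an order of magnitude; on simulated cohorts it
rejects ≥ 95% of artifact days while retaining ≥ 99% of clean days.

A patient is **included** iff analyzable days / scheduled monitoring days ≥
65%. The denominator is all 45 scheduled days (missing days count against
the ratio), so inclusion requires ≥ 30 analyzable days — 29/45 = 64.4%
fails, 30/45 = 66.7% passes.

## Adaptive alert detector

* **Learning**: expected-normal level = mean of analyzable indices on days
  1..`learning_days` (default 4). A patient with no analyzable learning-day
  measurement is excluded from detection with an explicit status.
* **Normal range**: multiplicative band level · (1 ± h),
  h = `range_halfwidth_fraction` = 0.10, standing in for prior knowledge of
  normal index variability in stable ambulatory HF patients. The interval
  is closed: boundary values are normal.
* **Classification**: each analyzable day after the learning period is
  `normal`, `abnormal_low` or `abnormal_high` against the band in effect
  that day; absent/non-analyzable days are `unclassified`.
* **Adaptation**: after a *normal* day, level ← (1 − a)·level + a·index
  with a = `adaptation_rate` = 0.1. Abnormal days never update the level,
  so a developing decompensation cannot drag its own reference down
  (verified as a property test). a = 0 disables adaptation.
* **Alert**: raised on every day ending a run of ≥ `run_length` = 3
  consecutive calendar days each with an analyzable `abnormal_low`
  classification. Missing, non-analyzable, normal and `abnormal_high` days
  all reset the run (three consecutive *values* below range are required).
  Earliest possible alert: day `learning_days + run_length` = 7.

Open design points resolved here (the published algorithm is not specified
at this level): the run resets on missing days rather than skipping them;
adaptation acts on normal days only; the band is symmetric but only the low
side alerts. All three sit behind `DetectorConfig`.

### Detectability of a linear decline

An exponentially-adapting level tracks a linear ramp of relative slope *s*
per day with steady-state lag s·(1 − a)/a. The band is outrun — i.e. days
start classifying abnormal_low — only when that lag exceeds h, giving the
detectability condition

    s > h · a / (1 − a)  ≈ 1.11%/day at the defaults (h = 0.10, a = 0.1).

A 15%/14-day decline (1.07%/day) is silently tracked; the default 25%/14-day
decline (1.79%/day) is detected. This interaction between adaptation rate,
band width and decline speed is the central operating trade-off of the
detector and the reason slow congestion build-ups can evade adaptive-band
telemonitoring.

## Day-level evaluation

Windows both end the day before the event day: the **detection window** is
the D = 30 days before an event (an alert there is clinically early-true),
the **critical window** the W = 3 days before (a silent day there is an
actionable miss). Per evaluable day, with window membership a union over
the patient's events: TP = alert ∧ in-detection; FP = alert ∧ ¬in-detection;
FN = ¬alert ∧ in-critical; TN otherwise. Counts pool over patients;
sensitivity = TP/(TP+FN), specificity = TN/(TN+FP), accuracy = (TP+TN)/N,
with Wilson score 95% CIs on the pooled day counts (the study-style
convention; days within a patient are correlated, so a patient-level
cluster bootstrap CI is provided as an option). Undefined rates (zero
denominator) are explicit `None` markers.

**Evaluable days** default to `learning_days + run_length` .. 45 (7..45):
counting the warm-up days, on which no alert is possible by construction,
as true negatives would inflate specificity. `include_warmup_days=True`
restores the all-45-day convention. Events on days 46..75 contribute the
part of their windows intersecting the evaluable range; an event whose
detection window misses it entirely is not evaluable — hence the number of
subjects with evaluable events can grow with D in the window grid.

**Lead time** per event = event day − first alert day inside that event's
detection window; mean/median are over events with at least one in-window
alert. The **window grid** evaluates all (D, W) ∈ {14, 21, 30} × {3, 7, 14}
cells. Provable monotonicities (tested by brute force): at fixed alerts and
events, sensitivity is non-increasing in W and non-decreasing in D;
specificity is non-decreasing in D.

## Problem sizes and numerical choices

Tests run cohorts of 5–300 patients for generator statistics, 1000 random
instances for each brute-force oracle equivalence, a 200-patient
strong-signal cohort and two 60-patient null cohorts for end-to-end
recovery, and 100 random parameter draws for the noiseless Cole round-trip
(tolerance 1e-3 relative; the fits land orders of magnitude inside it).
The strong-signal configuration (decline 50%/14 days, recovery 3 days,
cv = 0.005, no missingness) was designed from the detectability analysis
above so that alerts cover each event's critical window even when the
decline overlaps the learning period, and post-event recovery contributes at
most ~2 false-positive days per event — yielding day-level sensitivity and
specificity ≥ 0.95. On null (event-free) cohorts the ±10% band sits ≈ 5
lognormal standard deviations from the mean at cv = 0.02, so the false-alarm
day rate is ≈ 0 and is checked against an independently seeded calibration
cohort within 3 binomial standard errors.

Ties and edges: boundary index values are normal; the at-threshold QC
residual is analyzable; flat spectra fit to the degenerate boundary and are
flagged; empty timelines fail inclusion without error.

## Known limitations

* The index definition (R_0) and the band half-width are design choices,
  not published constants; real-device index construction may differ.
* Pooled-day CIs understate uncertainty under within-patient correlation;
  the cluster bootstrap is the honest alternative.
* The generator's noise is day-to-day independent; real bioimpedance series
  show autocorrelation and posture/hydration artifacts that would raise the
  false-alarm rate relative to these simulations.
* With the default adaptation rate, declines slower than ≈ 1.1%/day are
  tracked, not alerted; detecting slow congestion requires a smaller
  adaptation rate or a drift-aware detector, both outside scope.
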