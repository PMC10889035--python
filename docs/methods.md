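# Methods

This note documents the models, rules, and design choices behind `pdprog`:
what each stage computes, what the synthetic-data generator does and does
not emulate, and the numerical conventions used throughout.

## Data model and time conventions

All dates are integer days since a dataset-declared epoch; intervals are
half-open `[start, end)` except where a rule is explicitly inclusive. This
makes the 730/180/90/30-day phenotyping rules exact integer arithmetic.
Research-style cohorts record only the *year* of diagnosis; the convention
is that year *Y* maps to July 1 of *Y*, and all derived durations for such
patients are reported at whole-year resolution (`floor(days/365.25)`).
Consequently a research-arm Kaplan–Meier median can legitimately be 0 years.

Rating scales and valid ranges: modified Hoehn & Yahr on the grid
{0, 1, 1.5, 2, 2.5, 3, 4, 5}; MMSE and MoCA integers 0–30; UPDRS total
integers 0–199 (the original full-scale maximum — which UPDRS version
underlies a given dataset is configuration, and the bound is deliberately
permissive). Extractor outputs outside a scale's range are treated as
extraction failures, never as data.

Drug identity is normalized to a small set of drug classes (levodopa, other
PD therapeutic, cognition medication, other) at ingestion; mapping from
national drug codes is a configuration table, not code, because those
vocabularies are licensing-dependent.

## Cohort definition

Four filters in fixed order: PD code → quiescence → confirmation → mimic
exclusion. All four are evaluated for every patient (so exclusion reasons
are complete diagnostics), while attrition counts follow the sequential
order. Choices made where the rules leave room:

* The 730-day boundary is inclusive: coverage starting exactly 730 days
  before the index passes. Flagged as a sensitivity-analysis knob.
* "Continuous coverage" is taken from the declared coverage window, not
  reconstructed from claim gaps — enrollment is a dataset property.
* The mimic-exclusion window is `[index−730, index]` *inclusive* of the
  index day: a mimic diagnosis on the index day excludes (conservative).
* Mimic-condition and adverse-event code lists are configurable; the
  shipped defaults are compact stand-in sets per condition family
  (encephalitis, Alzheimer's, schizophrenia, Wilson's disease, MSA/PSP),
  sufficient to exercise the logic. Production use should supply
  site-curated lists.
* Patients with a stated diagnosis year bypass quiescence and confirmation
  (their diagnosis is known, not phenotyped) but still appear in the
  attrition table.

## Medication initiation

The detector scans candidate first fills chronologically and returns the
earliest fill *f* such that (a) *f*'s day carries a PD-coded encounter,
(b) the class-filtered fills in `[f, f+180]` number ≥ 2 with span
strictly > 90 days, and (c) their summed days supplied strictly exceed 90.
Conventions: "within 180 days" is inclusive, both 90-day thresholds are
strict; days supplied are summed only inside the window, so isolated trial
fills never accumulate into an initiation; "linked to an encounter with a
PD diagnosis" is operationalized as a same-calendar-day PD-coded encounter
(claims fills lack reliable encounter links; same-day is the reproducible
proxy). The whole-window scan is provably equivalent to accepting any
qualifying fill subsequence (any subset with span > 90 and supply > 90
implies the enclosing window qualifies), and the test suite verifies this
against exhaustive subset enumeration on random histories.

## Clinical events and censoring

* **Cognitive decline (real-world proxy):** earliest post-index MCI code
  (331.83/G31.84), cognition-medication fill on a PD-coded-encounter day,
  or a configured neurology-referral (code, specialty) marker. The referral
  criterion has no default — configuration only.
* **Cognitive decline (MMSE):** first post-index MMSE ≤ 25 (inclusive).
  With no post-index MMSE the patient is censored at the index with a
  logged caveat.
* **Scale threshold (H&Y 3):** first post-index observation ≥ 3, censored
  at the last observation.
* **Adverse events (depression, falls/fractures):** an event code as
  primary or admitting diagnosis of a visit that is inpatient or carries a
  same-visit configured treatment (the treatment sets ship empty, so
  inpatient-only qualifies by default). Any event code during the
  quiescence window excludes the patient from that event's analysis
  entirely.
* **Censoring regimes:** claims-style at coverage end (disenrollment),
  EMR-style at the last encounter, research-style at the last study visit.
  Survey-style cohorts record event presence without dates and are omitted
  from all dated event types except self-reported therapy initiation;
  they are likewise excluded from levodopa-specific analyses, which they
  do not collect.

## Consensus extraction

Default policy: 10 runs per exemplar polarity, acceptance threshold 9,
assessed *per polarity* with both sets' modal values required to coincide
(a pooled mode is available; its threshold scales proportionally, 18/20 at
the defaults). Run outputs are numerically normalized before comparison
("2,5", "II.5" → 2.5); unparseable outputs count as non-matching failures
rather than NA. Modal ties flag, polarity disagreements flag, accepted
non-NA values must pass the scale's range check or they flag as
out-of-range. The decision is invariant to run order and monotone in the
threshold.

The reference extractor is rule-based pattern matching over the documented
surface forms per scale. On notes carrying two distinct values for one
scale it deliberately returns the first-mentioned value for even variant
ids and the last for odd ones, so ambiguity produces a 5-vs-5 split and a
flag — mirroring how a generative extractor disagrees with itself on
genuinely ambiguous notes. It is exact on single-mention notes, which is
what makes end-to-end extraction accuracy on synthetic corpora a sharp
test rather than a benchmark of cleverness.

## Statistics

* **Test selection:** Shapiro–Wilk on each sample; if both retain
  normality at α = 0.05, Levene's p is recorded and Welch's
  (unequal-variance) *t*-test gives the final p — Welch remains valid under
  equal variances, so the Levene outcome does not branch. Otherwise a
  two-sided Mann–Whitney U.
* **Survival:** Kaplan–Meier product-limit estimates and the unstratified
  two-group log-rank test, both delegated to `lifelines`. The median is the
  earliest time with survival ≤ 0.5 and is reported as "> last time" when
  the curve never reaches 0.5. A comparison with zero observed events
  returns statistic 0, p = 1.
* **Progression model:** ordinary least squares of the score on years
  since diagnosis plus covariates (age at diagnosis, sex, education where
  collected); irregular visit spacing is handled by time-as-covariate, with
  no mixed effects. Covariates are mean-centered so the intercept is the
  expected score at diagnosis for a cohort-average patient. Diagnostics:
  Shapiro–Wilk on residuals, max VIF (acceptance bound 10) whenever the
  design has ≥ 2 predictors, Breusch–Pagan for homoscedasticity.
  Rank-deficient designs raise an error naming the collinear columns.
  Models are fit per cohort (the regimes are reported per cohort); no
  multiple-testing correction is applied, and reports say so implicitly by
  carrying raw p-values.
* **Phi coefficient:** computed from the 2×2 closed form; undefined (an
  error) when a margin is zero. Cross-checked in tests against the Pearson
  correlation of expanded 0/1 vectors.
* **Levodopa by stage:** for each H&Y stage, the fraction of patients whose
  initiation date precedes their first observation at that stage, among
  patients reaching it.

## Synthetic-data generator

The generator defines the study conditions; its defaults encode the
contrasts the pipeline is meant to measure:

| parameter | research-style | real-world-style |
|---|---|---|
| diagnosis age (mean ± sd) | 60.4 ± 9 | 72.2 ± 9 |
| follow-up mean (gamma, shape 2) | 6.1 y (survey 2.0 y) | 3.2 y |
| UPDRS slope / intercept | 1.54 / 28.25 | 3.87 / 18.93 |
| MMSE decline / intercept | 0.11 / 28.7 | 0.28 / 25.8 |
| H&Y-3 hazard (exp) | 0.055 /y (median ≈ 12.6 y) | 0.124 /y (median ≈ 5.6 y) |
| cognitive-decline hazard | 0.04 /y | 0.09 /y |
| therapy delay mean (exp) | 0.7 y | 3.0 y (+2.3 y) |
| score-in-note probability | — | 0.08 per EMR note |
| levodopa plateau by stage 2.5 | 0.85 | 0.85 |

Score trajectories are linear in years since diagnosis with patient-level
random intercepts and observation noise, clamped to scale ranges and
rounded to scale grids. The H&Y stage is a step trajectory reaching 3
exactly at the latent crossing time. Clinically recognized cognitive
decline is a latent exponential event *coupled* to the MMSE trajectory:
observed MMSE stays above the ≤ 25 threshold before onset and drops firmly
below it after, while the proxy code/fill appears a short recognition delay
(exp, mean 0.4 y) later — the delay is the designed source of
proxy-vs-MMSE disagreement, yielding φ ≈ 0.85–0.95 rather than a
degenerate 1.0. Two consequences worth knowing: with zero event hazards
every downstream event is censored (no noise-tail false crossings), and the
*study-level* fitted MMSE slope reflects the coupled trajectories, not the
configured linear decline. The configured declines are recovered exactly in
the raw-trajectory mode (`discretize_scores=False`, random-intercept sds 0),
which exists precisely to make regression-parameter recovery well-posed;
the recovery experiment uses UPDRS observation noise sd 8 and MMSE noise
sd 1 (each scale's own default).

Treated real-world patients receive a fill sequence that satisfies the
initiation criteria exactly at the true initiation day (fills at +0/+45/
+100 days with 30/60/30 days supplied, then maintenance refills), with an
optional isolated 90-day decoy fill 250 days earlier that never qualifies.
A configurable fraction of real-world patients violates each cohort rule
(short quiescence, missing confirmation, mimic code, no PD code; default
5% each) to exercise attrition, and a small fraction carries a
quiescence-window adverse-event code to exercise the prior-event exclusion.
Survey-style participants report therapy initiation at the diagnosis date
regardless of truth (the self-report bias knob) and record event presence
without dates.

What the generator does **not** emulate: realistic clinical language
(notes are template sentences), comorbidity co-occurrence structure,
informative missingness of note scores, dose/strength or adherence
patterns, and MoCA trajectories (the range checks and extraction patterns
cover MoCA, but the default cohorts do not emit it). Passing tests
therefore demonstrate the *algorithms* are correct under known conditions,
not that the pipeline is robust to real clinical text or to
outcome-dependent missingness.

## Problem sizes and determinism

The default study runs 600 patients per cohort — enough that every
directional contrast, including the sparsest (H&Y-3 crossing from the
~8%-of-notes extracted scores), is comfortably powered — and completes in
seconds. The recovery experiment refits both regimes on fresh data
(1,000 patients/arm per replicate); the log-rank calibration uses 200
patients/group under identical exponential hazards. Everything is driven
by a single integer seed through per-patient counter-based generators:
the same configuration and seed reproduce every table byte-for-byte
(numeric CSVs are written with fixed formatting; plots, when requested,
are excluded from determinism guarantees).

## Known limitations

* The pipeline treats extraction-accepted scores as equivalent to
  structured scores downstream; the usual caveat that score-bearing
  patients may be unrepresentative applies and is out of scope (the
  score-presence classifier is deliberately not implemented).
* No Cox regression, mixed-effects or spline progression models, and no
  causal adjustment for cohort selection — the comparison is descriptive.
* Long-term-care discharge and dyskinesia events are not implemented
  (no operational definition available); the neurology-referral criterion
  is configuration-only for the same reason.
* The UPDRS version ambiguity (original vs MDS revision) is resolved by a
  permissive 0–199 range; datasets mixing versions need harmonization
  upstream.
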