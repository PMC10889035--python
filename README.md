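# pdprog

Tools for comparing Parkinson's disease (PD) progression between
**research-style** populations (longitudinal studies with scheduled visits
and structured rating scores, or online self-surveys) and **real-world-style**
populations (hospital EMR and claims-EHR data, where everything must be
phenotyped from diagnosis codes, prescription fills, and free-text notes).

It is written for biostatisticians and pharmacoepidemiologists who need a
tested, reusable implementation of the full comparison pipeline — and,
because the real clinical datasets of this kind are access-restricted, it
ships a synthetic multi-cohort generator with known ground truth so every
stage can be exercised and validated end to end.

## What it implements

**EHR phenotyping.** A new-onset PD cohort definition with attrition
accounting: index at the first PD code (ICD-9 332/332.0, ICD-10 G20), a
730-day pre-index quiescence period (continuous coverage for claims data, an
encounter ≥ 730 days prior for EMR data), a confirmation PD code ≥ 30 days
post-index, and exclusion of parkinsonism-mimicking conditions diagnosed
during the quiescence window.

**Medication-initiation detection.** Therapy initiation is the first fill
*f* of a sequence satisfying all of: *f* falls on a day with a PD-coded
encounter; the fills in [*f*, *f*+180 d] number ≥ 2 and span > 90 days; and
they hold > 90 total days of pills. A single 90-day evaluation fill never
qualifies.

**Cognitive decline.** Two definitions: the MMSE cut-off (first score
≤ 25), and a composite real-world proxy (mild-cognitive-impairment code,
a cognition medication filled during a PD-coded encounter, or a configured
neurology-referral marker). Their agreement is validated with the phi
coefficient φ = (n₁₁n₀₀ − n₁₀n₀₁)/√(row and column margin products), the
Pearson correlation of the two binary indicators.

**Consensus note-score extraction.** A pluggable extractor contract is
fanned out over 10 score-bearing-exemplar and 10 score-free-exemplar prompt
variants per note; a value is accepted only when ≥ 9 of 10 runs per set
agree, anything less is flagged into a manual-review queue whose corrections
merge back as `source=manual` observations. A deterministic rule-based
reference extractor is included (exact on single-mention notes,
variant-sensitive on ambiguous ones so they flag).

**Statistics.** Normality-driven test selection (Shapiro–Wilk →
Levene → Welch's *t*, or Mann–Whitney U), Kaplan–Meier estimation and
two-group log-rank tests (via `lifelines`), and a covariate-adjusted linear
progression model — score ~ years-since-diagnosis + age at diagnosis + sex
(+ education where collected) — with residual-normality, VIF (< 10), and
homoscedasticity diagnostics (via `statsmodels`).

## Worked example

`examples/06_full_comparative_study.py` runs the whole pipeline on the
default synthetic cohorts (300 patients per style, seed 5):

```
Cohort summary:
             cohort  n_included  pct_male  age_mean  follow_up_mean
    research_survey         300     59.67     59.87            1.52
research_visitbased         300     64.33     60.29            5.59
         rwd_claims         237     61.60     72.93            3.36
            rwd_emr         245     58.78     72.56            3.03

Survival comparisons (pooled research vs pooled real-world):
                event_type median_research median_rwd    logrank_p
     pd_therapy_initiation               0    1.59069 1.014443e-65
       levodopa_initiation               1    1.97947 1.581929e-24
cognitive_decline_combined             >25    9.30048 2.445188e-03

Progression fits:
             cohort       scale  slope  intercept
research_visitbased UPDRS_total  1.452     28.433
            rwd_emr UPDRS_total  4.121     17.594

Proxy-vs-MMSE agreement: phi = 0.853
```

Reading the numbers: the real-world-style cohorts are diagnosed ~12 years
older, lose ~20% of patients to the phenotyping filters (n_included), start
PD therapy later (median 1.6 vs 0 years after diagnosis, log-rank
p < 10⁻⁶⁰; research times are reported at whole-year resolution because
those cohorts record only the diagnosis year), meet the cognitive-decline
definition sooner, and progress about 2.7 UPDRS points/year faster. The
φ of 0.85 says the code/medication proxy and the MMSE ≤ 25 definition
identify the same patients at the same visits almost always. The other
examples each demonstrate one stage in isolation.

A thin CLI wraps the same functions:
`pdprog simulate | cohort-build | extract-run | events-build | study-run`.

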