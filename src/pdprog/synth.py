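"""Synthetic multi-cohort generator with known ground truth.

Emulates four data-collection styles so every downstream stage is testable
without access-restricted clinical data:

* ``research_visitbased`` — in-person longitudinal study: explicit diagnosis
  year, scheduled annual visits with structured rating scores, staff-entered
  therapy-initiation dates, earlier diagnosis age (mean 60.4), long
  follow-up (mean 6.1 y), slow progression (UPDRS slope 1.54 from intercept
  28.25; MMSE decline 0.11/y from 28.7).
* ``research_survey`` — online self-survey study: explicit diagnosis year,
  event presence recorded without dates, and a self-report bias knob under
  which participants report starting PD therapy immediately at diagnosis.
* ``rwd_emr`` — hospital EMR: index date derivable only from codes
  (encounter-based quiescence), scores present only inside a small fraction
  of free-text notes (default 8% per note), later diagnosis age (mean
  72.2), short follow-up (3.2 y), fast progression (UPDRS slope 3.87 from
  18.93; MMSE decline 0.28/y from 25.8), censoring at the last encounter.
* ``rwd_claims`` — claims-EHR: coverage-based quiescence and censoring at
  disenrollment, prescription fills with days supplied, no notes or scores.

Score trajectories are linear in years since diagnosis with patient-level
random intercepts and observation noise, clamped to each scale's range and
rounded to its grid.  Clinically recognized cognitive decline is a latent
exponential event coupled to the MMSE trajectory (an extra drop below the
<= 25 impairment threshold once decline begins), so the composite
code/medication proxy and the MMSE definition agree strongly by
construction.  Therapy initiation is delayed in real-world styles (default
extra ~2.3 years on average) and the fill sequences emitted for treated
real-world patients satisfy the three initiation criteria exactly at the
true initiation date.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .model import (
    DAYS_PER_YEAR,
    ClinicalNote,
    DiagnosisEvent,
    Encounter,
    PatientRecord,
    PrescriptionFill,
    ScoreObservation,
    day_to_year,
    validate_range,
)

__all__ = [
    "CohortSimConfig",
    "SimConfig",
    "PatientTruth",
    "GroundTruth",
    "default_config",
    "generate_population",
    "embed_scores_in_notes",
    "generate_fills",
    "NOTE_TEMPLATES",
]

COHORT_STYLES = ("research_visitbased", "research_survey", "rwd_emr", "rwd_claims")


@dataclass
class CohortSimConfig:
    """Study conditions for one cohort style.  Defaults (set per style by
    :func:`default_config`) encode the published contrasts between research
    and real-world populations."""

    label: str
    n_patients: int = 600
    diagnosis_age_mean: float = 60.4
    diagnosis_age_sd: float = 9.0
    follow_up_mean_years: float = 6.1
    # linear score-trajectory parameters
    updrs_slope: float = 1.54
    updrs_intercept: float = 28.25
    updrs_noise_sd: float = 8.0
    updrs_intercept_sd: float = 4.0
    mmse_decline: float = 0.11
    mmse_intercept: float = 28.7
    mmse_noise_sd: float = 1.0
    mmse_intercept_sd: float = 0.8
    hy_baseline: float = 2.0
    # event hazards, per year
    hy3_hazard: float = 0.055
    cognitive_decline_hazard: float = 0.04
    cognition_recognition_delay_mean_years: float = 0.4
    depression_hazard: float = 0.05
    falls_hazard: float = 0.06
    prior_event_prob: float = 0.0
    # therapy
    treated_fraction: float = 0.9
    therapy_delay_mean_years: float = 0.7
    levodopa_extra_delay_mean_years: float = 0.4
    levodopa_plateau: float = 0.85
    decoy_fill_prob: float = 0.0
    # notes
    score_in_note_prob: float = 0.0
    note_ambiguity_rate: float = 0.0
    note_prob: float = 0.8
    # structure / bookkeeping
    rule_violation_fraction: float = 0.0
    self_report_immediate_start: bool = False
    #: round observed scores to each scale's grid and apply the latent
    #: cognitive-decline coupling; switch off for the raw linear-trajectory
    #: mode used in regression-parameter recovery studies.
    discretize_scores: bool = True

    def validate(self) -> None:
        probs = {
            "treated_fraction": self.treated_fraction,
            "levodopa_plateau": self.levodopa_plateau,
            "score_in_note_prob": self.score_in_note_prob,
            "note_ambiguity_rate": self.note_ambiguity_rate,
            "note_prob": self.note_prob,
            "decoy_fill_prob": self.decoy_fill_prob,
            "prior_event_prob": self.prior_event_prob,
            "rule_violation_fraction": self.rule_violation_fraction,
        }
        for name, p in probs.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{self.label}: {name}={p} outside [0, 1]")
        for name in ("diagnosis_age_sd", "updrs_noise_sd", "mmse_noise_sd"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{self.label}: {name} must be positive")
        if self.n_patients < 1:
            raise ValueError(f"{self.label}: n_patients must be >= 1")
        if self.label not in COHORT_STYLES:
            raise ValueError(f"unknown cohort style {self.label!r}")


@dataclass
class SimConfig:
    cohorts: dict[str, CohortSimConfig]
    seed: int = 0

    def validate(self) -> None:
        for label, cc in self.cohorts.items():
            if label != cc.label:
                raise ValueError(f"cohort key {label!r} != block label {cc.label!r}")
            cc.validate()


def default_config(n_per_cohort: int = 600, seed: int = 0, **overrides) -> SimConfig:
    """The default study conditions: research-style vs real-world-style
    contrasts in age, follow-up, progression, delays, and observability."""
    research = dict(
        diagnosis_age_mean=60.4, follow_up_mean_years=6.1,
        updrs_slope=1.54, updrs_intercept=28.25,
        mmse_decline=0.11, mmse_intercept=28.7,
        hy3_hazard=0.055, cognitive_decline_hazard=0.04,
        therapy_delay_mean_years=0.7,
    )
    rwd = dict(
        diagnosis_age_mean=72.2, follow_up_mean_years=3.2,
        updrs_slope=3.87, updrs_intercept=18.93,
        mmse_decline=0.28, mmse_intercept=25.8,
        hy3_hazard=0.124, cognitive_decline_hazard=0.09,
        therapy_delay_mean_years=3.0,
        rule_violation_fraction=0.05, prior_event_prob=0.03,
    )
    cohorts = {
        "research_visitbased": CohortSimConfig(
            label="research_visitbased", n_patients=n_per_cohort, **research),
        "research_survey": CohortSimConfig(
            label="research_survey", n_patients=n_per_cohort,
            self_report_immediate_start=True, follow_up_mean_years=2.0,
            **{k: v for k, v in research.items() if k != "follow_up_mean_years"}),
        "rwd_emr": CohortSimConfig(
            label="rwd_emr", n_patients=n_per_cohort,
            score_in_note_prob=0.08, note_ambiguity_rate=0.02,
            depression_hazard=0.05, falls_hazard=0.06, **rwd),
        "rwd_claims": CohortSimConfig(
            label="rwd_claims", n_patients=n_per_cohort,
            depression_hazard=0.10, falls_hazard=0.12, **rwd),
    }
    for key, value in overrides.items():
        for cc in cohorts.values():
            setattr(cc, key, value)
    return SimConfig(cohorts=cohorts, seed=seed)


@dataclass
class PatientTruth:
    patient_id: str
    cohort_label: str
    diagnosis_day: int
    diagnosis_age: float
    follow_up_years: float
    detectable: bool
    violation: str  # "", short_quiescence, no_confirmation, mimic, no_pd_code
    pd_therapy_init_day: int | None = None
    levodopa_init_day: int | None = None
    hy3_years: float = math.inf
    cognitive_decline_years: float = math.inf
    depression_years: float = math.inf
    falls_years: float = math.inf
    updrs_slope: float = 0.0
    updrs_intercept: float = 0.0
    mmse_decline: float = 0.0
    mmse_intercept: float = 0.0


@dataclass
class GroundTruth:
    patients: dict[str, PatientTruth] = field(default_factory=dict)
    config: SimConfig | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(t) for t in self.patients.values()])


# ---------------------------------------------------------------------------
# Note templates

NOTE_TEMPLATES: dict[str, list[str]] = {
    "HY": [
        "Hoehn & Yahr: {v}",
        "Hoehn and Yahr stage {v}",
        "H&Y stage {v}",
        "HY={v}",
        "Exam notable for H&Y {v} today",
    ],
    "MMSE": [
        "MMSE: {v}/30",
        "MMSE score {v}",
        "Mini-mental state exam {v} of 30",
        "mini-mental: {v}",
    ],
    "UPDRS_total": [
        "UPDRS total: {v}",
        "UPDRS total score of {v}",
        "total UPDRS {v} at this visit",
    ],
}

FILLER_SENTENCES = [
    "Patient seen in follow-up for Parkinson's disease.",
    "Tremor stable on current regimen.",
    "Gait steady with walker; no falls reported.",
    "Continues physical therapy twice weekly.",
    "No medication side effects reported today.",
    "Sleep improved; mood stable.",
]


def _format_value(scale: str, value: float) -> str:
    if scale == "UPDRS_total" or float(value).is_integer():
        return str(int(value))
    return f"{value:g}"


def _distinct_value(scale: str, value: float, rng: np.random.Generator) -> float:
    """A second, different valid value for the same scale (ambiguous notes)."""
    from .model import HY_GRID

    if scale == "HY":
        options = [v for v in HY_GRID if v != value and v > 0]
    elif scale in ("MMSE", "MoCA"):
        options = [v for v in range(0, 31) if v != value]
    else:
        options = [v for v in range(0, 200) if v != value]
    return float(options[int(rng.integers(0, len(options)))])


def embed_scores_in_notes(
    trajectory: list[tuple[int, str, float]],
    rng: np.random.Generator,
    templates: dict[str, list[str]] | None = None,
    ambiguity_rate: float = 0.0,
    score_in_note_prob: float = 1.0,
    note_id_prefix: str = "note",
) -> list[ClinicalNote]:
    """Turn (date, scale, value) trajectory points into clinical notes.

    With probability ``score_in_note_prob`` a note embeds the trajectory
    value through a randomly chosen surface form; with probability
    ``ambiguity_rate`` it embeds a second distinct value for the same scale.
    ``truth_scores`` records exactly what was embedded.  All embedded values
    pass the scale's range check by construction.
    """
    templates = templates if templates is not None else NOTE_TEMPLATES
    if not templates or any(not forms for forms in templates.values()):
        raise ValueError("template set must be non-empty for every scale")
    notes: list[ClinicalNote] = []
    for k, (date, scale, value) in enumerate(trajectory):
        note_id = f"{note_id_prefix}-{k:05d}"
        filler = FILLER_SENTENCES[int(rng.integers(0, len(FILLER_SENTENCES)))]
        if rng.random() >= score_in_note_prob:
            notes.append(ClinicalNote(note_id, date, filler, truth_scores={}))
            continue
        assert validate_range(scale, value), (scale, value)
        forms = templates[scale]
        text = filler + " " + forms[int(rng.integers(0, len(forms)))].format(
            v=_format_value(scale, value))
        embedded = [value]
        if rng.random() < ambiguity_rate:
            second = _distinct_value(scale, value, rng)
            text += ". Previously " + forms[int(rng.integers(0, len(forms)))].format(
                v=_format_value(scale, second))
            embedded.append(second)
        notes.append(
            ClinicalNote(note_id, date, text, truth_scores={scale: tuple(embedded)})
        )
    return notes


# ---------------------------------------------------------------------------
# Fill sequences

#: (day offset, days supplied) of the qualifying initiation sequence:
#: span 100 days (> 90, within 180) and 120 total days of pills (> 90).
_INITIATION_OFFSETS = ((0, 30), (45, 60), (100, 30))


def generate_fills(
    drug_class: str,
    init_day: int,
    follow_up_end: int,
    rng: np.random.Generator,
    decoy: bool = False,
) -> tuple[list[PrescriptionFill], list[int]]:
    """Fills for one treated drug class starting at the true initiation day.

    Returns the fills plus the days that must carry a PD-coded encounter
    (the first fill of the sequence, and the decoy day when present).  The
    emitted sequence satisfies the initiation criteria exactly at
    ``init_day``; the optional decoy is a single isolated 90-day fill 250
    days earlier that never qualifies (its 180-day window holds one fill).
    """
    fills: list[PrescriptionFill] = []
    pd_linked_days = [init_day]
    if decoy and init_day - 250 >= 0:
        fills.append(PrescriptionFill(drug_class, init_day - 250, 90))
        pd_linked_days.append(init_day - 250)
    for offset, supply in _INITIATION_OFFSETS:
        fills.append(PrescriptionFill(drug_class, init_day + offset, supply))
    day = init_day + 160
    while day + 60 <= follow_up_end:
        fills.append(PrescriptionFill(drug_class, day, 60))
        day += 60 + int(rng.integers(0, 15))
    return fills, pd_linked_days


# ---------------------------------------------------------------------------
# Trajectories


class _Trajectory:
    """Per-patient latent score trajectories with observation noise."""

    def __init__(self, cc: CohortSimConfig, hy3_years: float,
                 cog_years: float, rng: np.random.Generator):
        self.cc = cc
        self.hy3 = hy3_years
        self.cog = cog_years
        self.rng = rng
        self.b_updrs = rng.normal(0.0, cc.updrs_intercept_sd) if cc.updrs_intercept_sd else 0.0
        self.b_mmse = rng.normal(0.0, cc.mmse_intercept_sd) if cc.mmse_intercept_sd else 0.0

    def updrs(self, t: float) -> float:
        v = (self.cc.updrs_intercept + self.cc.updrs_slope * t + self.b_updrs
             + self.rng.normal(0.0, self.cc.updrs_noise_sd))
        if not self.cc.discretize_scores:
            return v
        return float(np.clip(round(v), 0, 199))

    def mmse(self, t: float) -> float:
        base = self.cc.mmse_intercept - self.cc.mmse_decline * t + self.b_mmse
        if not self.cc.discretize_scores:
            return base + self.rng.normal(0.0, self.cc.mmse_noise_sd)
        # couple to the latent cognitive-decline event: observed values stay
        # above the <= 25 impairment threshold before onset and drop firmly
        # below it after, so the threshold indicator tracks true onset
        v = base + self.rng.normal(0.0, self.cc.mmse_noise_sd)
        if t < self.cog:
            return float(np.clip(round(v), 26, 30))
        return float(np.clip(round(v - 5.0), 0, 30))

    def hy(self, t: float) -> float:
        if t < self.hy3 / 2:
            return self.cc.hy_baseline
        if t < self.hy3:
            return min(self.cc.hy_baseline + 0.5, 2.5)
        return float(min(3 + math.floor((t - self.hy3) / 2.5), 5))

    def value(self, scale: str, t: float) -> float:
        return {"HY": self.hy, "MMSE": self.mmse, "UPDRS_total": self.updrs}[scale](t)


# ---------------------------------------------------------------------------
# Patient generation


def _assign_violation(cc: CohortSimConfig, rng: np.random.Generator) -> str:
    v = cc.rule_violation_fraction
    if v == 0.0:
        return ""
    u = rng.random()
    for k, name in enumerate(
        ("short_quiescence", "no_confirmation", "mimic", "no_pd_code")
    ):
        if u < (k + 1) * v:
            return name
    return ""


def _gen_patient(
    cc: CohortSimConfig, i: int, seed: int, cohort_idx: int
) -> tuple[PatientRecord, PatientTruth]:
    rng = np.random.default_rng([seed % (2**31), cohort_idx, i])
    style = cc.label
    research = style.startswith("research")

    pid = f"{style}-{i:05d}"
    index = int(rng.integers(3000, 5000))
    age = float(rng.normal(cc.diagnosis_age_mean, cc.diagnosis_age_sd))
    birth = index - round(age * DAYS_PER_YEAR)
    fu_years = max(0.3, float(rng.gamma(2.0, cc.follow_up_mean_years / 2.0)))
    end = index + round(fu_years * DAYS_PER_YEAR)

    violation = "" if research else _assign_violation(cc, rng)
    can_add_pd_codes = violation not in ("no_confirmation", "no_pd_code")

    if violation == "short_quiescence":
        cov_start = index - int(rng.integers(30, 730))
    else:
        cov_start = index - 730 - int(rng.integers(0, 1500))

    rec = PatientRecord(
        patient_id=pid,
        sex="male" if rng.random() < 0.6 else "female",
        birth_date=birth,
        coverage_start=cov_start,
        coverage_end=end,
        cohort_label=style,
        education_years=(
            int(np.clip(round(rng.normal(16, 2.5)), 8, 22)) if research else None
        ),
    )

    eid = 0

    def add_encounter(date: int, setting: str = "outpatient",
                      specialty: str = "") -> Encounter:
        nonlocal eid
        date = int(np.clip(date, cov_start, end - 1))
        enc = Encounter(f"{pid}-e{eid:04d}", date, setting, specialty)
        eid += 1
        rec.encounters.append(enc)
        return enc

    def add_pd_code(date: int) -> None:
        enc = add_encounter(date, specialty="neurology")
        rec.diagnoses.append(DiagnosisEvent("G20", enc.date, enc.encounter_id))

    # latent event times (years from diagnosis)
    def draw_event(hazard: float) -> float:
        return float(rng.exponential(1.0 / hazard)) if hazard > 0 else math.inf

    hy3_t = draw_event(cc.hy3_hazard)
    cog_t = draw_event(cc.cognitive_decline_hazard)
    dep_t = draw_event(cc.depression_hazard)
    fall_t = draw_event(cc.falls_hazard)

    traj = _Trajectory(cc, hy3_t, cog_t, rng)

    # therapy initiation
    treated = rng.random() < cc.treated_fraction and can_add_pd_codes
    pd_init_t = ld_init_t = None
    if treated:
        pd_init_t = float(rng.exponential(cc.therapy_delay_mean_years))
        ld_init_t = pd_init_t + float(
            rng.exponential(cc.levodopa_extra_delay_mean_years))
        t25 = hy3_t / 2  # time of first reaching stage 2.5
        if t25 < fu_years:
            if rng.random() < cc.levodopa_plateau:
                if ld_init_t > t25:
                    ld_init_t = float(rng.uniform(0, t25))
                    pd_init_t = min(pd_init_t, ld_init_t)
            elif ld_init_t <= t25:
                ld_init_t = t25 + float(rng.uniform(0.2, 1.0))

    truth = PatientTruth(
        patient_id=pid, cohort_label=style, diagnosis_day=index,
        diagnosis_age=age, follow_up_years=fu_years,
        detectable=(violation == ""), violation=violation,
        hy3_years=hy3_t, cognitive_decline_years=cog_t,
        depression_years=dep_t, falls_years=fall_t,
        updrs_slope=cc.updrs_slope,
        updrs_intercept=cc.updrs_intercept + traj.b_updrs,
        mmse_decline=cc.mmse_decline,
        mmse_intercept=cc.mmse_intercept + traj.b_mmse,
    )

    if research:
        rec.diagnosis_year = day_to_year(index)
        n_visits = int(fu_years) + 1
        if style == "research_visitbased":
            for k in range(n_visits):
                t = float(k)
                visit_day = index + round(t * DAYS_PER_YEAR)
                if visit_day >= end:
                    break
                add_encounter(visit_day, specialty="neurology")
                for scale in ("HY", "MMSE", "UPDRS_total"):
                    rec.scores.append(ScoreObservation(
                        scale, traj.value(scale, t), visit_day, "structured"))
            if treated:
                pd_day = index + round(pd_init_t * DAYS_PER_YEAR)
                ld_day = index + round(ld_init_t * DAYS_PER_YEAR)
                if pd_day < end:
                    rec.reported_therapy_start["pd_therapy"] = pd_day
                if ld_day < end:
                    rec.reported_therapy_start["levodopa"] = ld_day
            truth.pd_therapy_init_day = rec.reported_therapy_start.get("pd_therapy")
            truth.levodopa_init_day = rec.reported_therapy_start.get("levodopa")
        else:  # research_survey
            for k in range(n_visits):
                day = index + round(k * DAYS_PER_YEAR)
                if day < end:
                    add_encounter(day, specialty="survey")
            if treated:
                reported = index if cc.self_report_immediate_start else (
                    index + round(pd_init_t * DAYS_PER_YEAR))
                rec.reported_therapy_start["pd_therapy"] = min(reported, end - 1)
                truth.pd_therapy_init_day = index + round(pd_init_t * DAYS_PER_YEAR)
            present = []
            if dep_t < fu_years:
                present.append("depression")
            if fall_t < fu_years:
                present.append("falls_fractures")
            if cog_t < fu_years:
                present.append("cognitive_decline")
            rec.reported_events = tuple(present)
        rec.sort_lists()
        return rec, truth

    # ------ real-world styles ------
    # pre-index encounters: one anchoring the coverage start, then sparse
    day = cov_start
    while day < index - 30:
        add_encounter(day)
        day += int(rng.integers(90, 240))
    # index diagnosis
    if violation != "no_pd_code":
        add_pd_code(index)
        if violation != "no_confirmation":
            add_pd_code(index + 30 + int(rng.integers(0, 70)))
    if violation == "mimic":
        mimic_code = "G30.9"  # Alzheimer's stand-in from the exclusion lists
        enc = add_encounter(index - int(rng.integers(0, 731)))
        rec.diagnoses.append(DiagnosisEvent(mimic_code, enc.date, enc.encounter_id))

    # routine post-index encounters (notes attach to these for EMR style)
    post_days = []
    day = index + int(rng.integers(30, 120))
    while day < end:
        post_days.append(day)
        add_encounter(day)
        day += int(rng.integers(60, 120))

    # adverse events
    for event_name, t in (("depression", dep_t), ("falls_fractures", fall_t)):
        code = {"depression": "F32.9", "falls_fractures": "W19"}[event_name]
        if cc.prior_event_prob and rng.random() < cc.prior_event_prob:
            enc = add_encounter(index - int(rng.integers(1, 730)), "inpatient")
            rec.diagnoses.append(
                DiagnosisEvent(code, enc.date, enc.encounter_id, "primary"))
        elif t < fu_years:
            enc = add_encounter(index + round(t * DAYS_PER_YEAR), "inpatient")
            rec.diagnoses.append(
                DiagnosisEvent(code, enc.date, enc.encounter_id, "primary"))

    # cognitive decline proxy signal; clinical recognition (the code or the
    # cognition-medication fill) lags true onset by a short delay, which is
    # the main source of proxy-vs-MMSE disagreement
    recognized_t = cog_t + float(
        rng.exponential(cc.cognition_recognition_delay_mean_years))
    if recognized_t < fu_years:
        cog_day = index + round(recognized_t * DAYS_PER_YEAR)
        if can_add_pd_codes and rng.random() < 0.5:
            add_pd_code(cog_day)
            rec.fills.append(
                PrescriptionFill("cognition_medication", cog_day, 30))
        else:
            enc = add_encounter(cog_day, specialty="neurology")
            rec.diagnoses.append(
                DiagnosisEvent("G31.84", enc.date, enc.encounter_id))

    # therapy fill sequences
    if treated:
        pd_day = index + round(pd_init_t * DAYS_PER_YEAR)
        ld_day = index + round(ld_init_t * DAYS_PER_YEAR)
        same = (ld_init_t - pd_init_t) < 0.15
        # a pre-initiation decoy must stay post-index so it cannot shift the
        # phenotyped index date
        decoy = (cc.decoy_fill_prob > 0 and rng.random() < cc.decoy_fill_prob
                 and min(pd_day, ld_day) - 250 > index)
        if same:
            if ld_day + 181 < end:
                fills, link_days = generate_fills("levodopa", ld_day, end, rng,
                                                  decoy=decoy)
                rec.fills.extend(fills)
                for d in link_days:
                    add_pd_code(d)
                truth.pd_therapy_init_day = ld_day
                truth.levodopa_init_day = ld_day
        else:
            if pd_day + 181 < end:
                fills, link_days = generate_fills("other_pd_therapeutic", pd_day,
                                                  end, rng, decoy=decoy)
                rec.fills.extend(fills)
                for d in link_days:
                    add_pd_code(d)
                truth.pd_therapy_init_day = pd_day
            if ld_day + 181 < end:
                fills, link_days = generate_fills("levodopa", ld_day, end, rng)
                rec.fills.extend(fills)
                for d in link_days:
                    add_pd_code(d)
                truth.levodopa_init_day = ld_day
                if truth.pd_therapy_init_day is None:
                    truth.pd_therapy_init_day = ld_day

    # notes with occasionally embedded scores (EMR style only)
    if style == "rwd_emr" and post_days:
        scales = ("HY", "MMSE", "UPDRS_total")
        trajectory_points = []
        for day in post_days:
            if rng.random() >= cc.note_prob:
                continue
            t = (day - index) / DAYS_PER_YEAR
            scale = scales[int(rng.integers(0, len(scales)))]
            trajectory_points.append((day, scale, traj.value(scale, t)))
        rec.notes.extend(embed_scores_in_notes(
            trajectory_points, rng,
            ambiguity_rate=cc.note_ambiguity_rate,
            score_in_note_prob=cc.score_in_note_prob,
            note_id_prefix=f"{pid}-n",
        ))

    rec.sort_lists()
    return rec, truth


def generate_population(config: SimConfig) -> tuple[list[PatientRecord], GroundTruth]:
    """Generate all configured cohorts; reproducible given the seed."""
    config.validate()
    records: list[PatientRecord] = []
    truth = GroundTruth(config=config)
    for cohort_idx, (label, cc) in enumerate(sorted(config.cohorts.items())):
        for i in range(cc.n_patients):
            rec, t = _gen_patient(cc, i, config.seed, cohort_idx)
            records.append(rec)
            truth.patients[rec.patient_id] = t
    return records, truth
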