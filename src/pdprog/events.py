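"""Time-to-event derivation from phenotyped patient records.

Covers the medication-initiation fill-sequence algorithm, the composite
cognitive-decline proxy, the MMSE cut-off definition, scale-threshold
crossings (H&Y stage 3), and the utilization-based adverse-event rule with
its quiescence-period exclusion, assembled into a per-patient event table.

Censoring follows each cohort style's observability: claims-style cohorts
censor at coverage end (disenrollment), EMR-style at the last encounter,
research-style at the last study visit.  Survey-style cohorts record event
presence without dates and are therefore omitted from dated event types.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import pandas as pd

from .cohort import QUIESCENCE_DAYS, CohortEntry
from .model import DAYS_PER_YEAR, CodeListConfig, PatientRecord, PrescriptionFill

__all__ = [
    "EventTime",
    "InitiationParams",
    "EVENT_TYPES",
    "detect_medication_initiation",
    "detect_cognitive_decline_proxy",
    "detect_cognitive_decline_mmse",
    "detect_scale_threshold",
    "detect_adverse_event",
    "build_event_table",
]

logger = logging.getLogger(__name__)

EVENT_TYPES = (
    "pd_therapy_initiation",
    "levodopa_initiation",
    "cognitive_decline_proxy",
    "cognitive_decline_mmse",
    "hy_stage3",
    "depression",
    "falls_fractures",
)


@dataclass(frozen=True)
class EventTime:
    patient_id: str
    event_type: str
    time_from_index: int  # days
    observed: bool
    excluded_for_prior_event: bool = False

    @property
    def years(self) -> float:
        return self.time_from_index / DAYS_PER_YEAR

    @property
    def whole_years(self) -> int:
        return math.floor(self.time_from_index / DAYS_PER_YEAR)


@dataclass(frozen=True)
class InitiationParams:
    """Three-criterion fill-sequence thresholds: a PD-linked first fill,
    > 90 total days supplied (strict), and 2+ fills spanning > 90 days
    (strict) but within 180 days (inclusive) of the first fill."""

    min_total_days: int = 90
    min_span_days: int = 90
    max_span_days: int = 180
    min_fills: int = 2
    require_pd_linked_first_fill: bool = True

    def __post_init__(self):
        if self.min_span_days >= self.max_span_days:
            raise ValueError("min_span_days must be < max_span_days")


def _classes_for(drug_class_filter: str) -> frozenset[str]:
    if drug_class_filter == "levodopa":
        return frozenset({"levodopa"})
    if drug_class_filter == "any_pd":
        return frozenset({"levodopa", "other_pd_therapeutic"})
    raise ValueError(f"unknown drug class filter {drug_class_filter!r}")


def detect_medication_initiation(
    fills: list[PrescriptionFill],
    pd_encounter_days: set[int],
    drug_class_filter: str = "any_pd",
    params: InitiationParams = InitiationParams(),
) -> int | None:
    """First date of a qualifying prescription-fill sequence, or None.

    Scanning candidate first fills chronologically, a candidate ``f``
    qualifies when (a) its day carries a PD-coded encounter, (b) the
    class-filtered fills in ``[f, f+max_span]`` number at least ``min_fills``
    and span strictly more than ``min_span`` days, and (c) their cumulative
    days supplied strictly exceed ``min_total_days``.  Days supplied are
    counted only inside the window, so isolated trial fills never accumulate
    into an initiation.
    """
    classes = _classes_for(drug_class_filter)
    relevant = sorted(
        (f for f in fills if f.drug_class in classes), key=lambda f: f.date
    )
    for i, first in enumerate(relevant):
        if params.require_pd_linked_first_fill and first.date not in pd_encounter_days:
            continue
        window = [
            g for g in relevant[i:] if g.date <= first.date + params.max_span_days
        ]
        if len(window) < params.min_fills:
            continue
        if window[-1].date - first.date <= params.min_span_days:
            continue
        if sum(g.days_supplied for g in window) <= params.min_total_days:
            continue
        return first.date
    return None


def _follow_up_end(patient: PatientRecord, style: str) -> int:
    """End of observability per censoring regime."""
    if style == "rwd_claims":
        _, end = patient.inferred_coverage()
        if end is None:
            raise ValueError(f"{patient.patient_id}: no coverage end for claims style")
        return end
    # EMR- and research-style: last encounter / last study visit
    if patient.encounters:
        return max(e.date for e in patient.encounters)
    _, end = patient.inferred_coverage()
    if end is None:
        raise ValueError(f"{patient.patient_id}: no encounters and no coverage end")
    return end


def detect_cognitive_decline_proxy(
    patient: PatientRecord,
    index: int,
    codes: CodeListConfig,
    follow_up_end: int,
) -> EventTime:
    """Composite real-world cognitive-decline definition.

    Event at the earliest post-index occurrence of (a) a mild-cognitive-
    impairment diagnosis code, (b) a cognition-medication fill on a day with
    a PD-coded encounter, or (c) the configured neurology-referral marker;
    censored at follow-up end otherwise.
    """
    candidates: list[int] = []
    candidates += [
        d.date for d in patient.diagnoses
        if d.code in codes.cognitive_decline_codes and d.date >= index
    ]
    pd_days = patient.pd_encounter_days(codes.pd_codes)
    candidates += [
        f.date for f in patient.fills
        if f.drug_class == "cognition_medication"
        and f.date >= index and f.date in pd_days
    ]
    if codes.neurology_referral_marker is not None:
        ref_code, ref_specialty = codes.neurology_referral_marker
        enc_by_id = {e.encounter_id: e for e in patient.encounters}
        for d in patient.diagnoses:
            if d.code == ref_code and d.date >= index:
                enc = enc_by_id.get(d.encounter_id or "")
                if enc is not None and enc.specialty == ref_specialty:
                    candidates.append(d.date)
    if candidates:
        return EventTime(patient.patient_id, "cognitive_decline_proxy",
                         min(candidates) - index, True)
    return EventTime(patient.patient_id, "cognitive_decline_proxy",
                     max(follow_up_end - index, 0), False)


def detect_cognitive_decline_mmse(
    score_obs, index: int, patient_id: str = "", cutoff: float = 25.0
) -> EventTime:
    """First post-index MMSE at or below the global-impairment cut-off
    (<= 25); censored at the last MMSE date otherwise."""
    mmse = sorted(
        (s for s in score_obs if s.scale == "MMSE" and s.date >= index),
        key=lambda s: s.date,
    )
    if not mmse:
        logger.info("%s: no post-index MMSE; censored at index", patient_id)
        return EventTime(patient_id, "cognitive_decline_mmse", 0, False)
    for s in mmse:
        if s.value <= cutoff:
            return EventTime(patient_id, "cognitive_decline_mmse", s.date - index, True)
    return EventTime(patient_id, "cognitive_decline_mmse", mmse[-1].date - index, False)


def detect_scale_threshold(
    score_obs,
    index: int,
    patient_id: str = "",
    scale: str = "HY",
    threshold: float = 3.0,
    event_type: str = "hy_stage3",
) -> EventTime:
    """First post-index observation at or above ``threshold`` for ``scale``;
    censored at the last observation otherwise."""
    obs = sorted(
        (s for s in score_obs if s.scale == scale and s.date >= index),
        key=lambda s: s.date,
    )
    if not obs:
        return EventTime(patient_id, event_type, 0, False)
    for s in obs:
        if s.value >= threshold:
            return EventTime(patient_id, event_type, s.date - index, True)
    return EventTime(patient_id, event_type, obs[-1].date - index, False)


def detect_adverse_event(
    patient: PatientRecord,
    index: int,
    event_name: str,
    codes: CodeListConfig,
    follow_up_end: int,
    quiescence: int = QUIESCENCE_DAYS,
) -> EventTime:
    """Utilization-based adverse-event rule with quiescence exclusion.

    A patient with any event code in ``[index-quiescence, index)`` is
    excluded from this event's analysis.  Otherwise the event occurs at the
    earliest post-index diagnosis bearing the event code as the primary or
    admitting code of a visit that is inpatient or carries a same-visit
    qualifying treatment (configured per event; empty config means only
    inpatient visits qualify).
    """
    code_set = codes.event_code_sets[event_name]
    if any(index - quiescence <= d.date < index and d.code in code_set
           for d in patient.diagnoses):
        return EventTime(patient.patient_id, event_name, 0, False,
                         excluded_for_prior_event=True)
    treatments = codes.event_treatment_codes.get(event_name, set())
    enc_by_id = {e.encounter_id: e for e in patient.encounters}
    hits: list[int] = []
    for d in patient.diagnoses:
        if d.code not in code_set or d.date < index:
            continue
        if d.position not in ("primary", "admitting"):
            continue
        enc = enc_by_id.get(d.encounter_id or "")
        inpatient = enc is not None and enc.setting == "inpatient"
        treated = bool(treatments) and any(
            f.encounter_id == d.encounter_id and f.drug_class in treatments
            for f in patient.fills
        )
        if inpatient or treated:
            hits.append(d.date)
    if hits:
        return EventTime(patient.patient_id, event_name, min(hits) - index, True)
    return EventTime(patient.patient_id, event_name,
                     max(follow_up_end - index, 0), False)


# ---------------------------------------------------------------------------
# Per-cohort capability map: which event types each data-collection style
# can support with dated observations.

_STYLE_EVENTS = {
    "research_visitbased": {
        "pd_therapy_initiation", "levodopa_initiation",
        "cognitive_decline_mmse", "hy_stage3",
    },
    "research_survey": {"pd_therapy_initiation"},
    "rwd_emr": {
        "pd_therapy_initiation", "levodopa_initiation", "cognitive_decline_proxy",
        "cognitive_decline_mmse", "hy_stage3", "depression", "falls_fractures",
    },
    "rwd_claims": {
        "pd_therapy_initiation", "levodopa_initiation", "cognitive_decline_proxy",
        "depression", "falls_fractures",
    },
}


def _reported_initiation(
    patient: PatientRecord, key: str, index: int, end: int, event_type: str
) -> EventTime:
    start = patient.reported_therapy_start.get(key)
    if start is not None:
        return EventTime(patient.patient_id, event_type, max(start - index, 0), True)
    return EventTime(patient.patient_id, event_type, max(end - index, 0), False)


def build_event_table(
    cohort: list[CohortEntry],
    records_by_id: dict[str, PatientRecord],
    codes: CodeListConfig | None = None,
    params: InitiationParams = InitiationParams(),
) -> pd.DataFrame:
    """One row per included patient x supported event type.

    Research-style cohorts use their stated initiation dates and structured
    scores; real-world-style cohorts use the fill-sequence detector and the
    code-based definitions.  Survey-style cohorts are omitted from event
    types they cannot date (all but self-reported therapy initiation).
    """
    codes = codes or CodeListConfig()
    rows: list[EventTime] = []
    year_granularity: dict[str, bool] = {}
    for entry in cohort:
        if not entry.included or entry.index_date is None:
            continue
        patient = records_by_id[entry.patient_id]
        style = entry.cohort_label or "rwd_emr"
        supported = _STYLE_EVENTS.get(style, _STYLE_EVENTS["rwd_emr"])
        index = entry.index_date
        end = max(_follow_up_end(patient, style), index)
        year_granularity[entry.patient_id] = entry.year_granularity

        if "pd_therapy_initiation" in supported:
            if style.startswith("research"):
                rows.append(_reported_initiation(
                    patient, "pd_therapy", index, end, "pd_therapy_initiation"))
            else:
                day = detect_medication_initiation(
                    patient.fills, patient.pd_encounter_days(codes.pd_codes),
                    "any_pd", params)
                rows.append(
                    EventTime(patient.patient_id, "pd_therapy_initiation",
                              max(day - index, 0), True) if day is not None
                    else EventTime(patient.patient_id, "pd_therapy_initiation",
                                   max(end - index, 0), False))
        if "levodopa_initiation" in supported:
            if style.startswith("research"):
                rows.append(_reported_initiation(
                    patient, "levodopa", index, end, "levodopa_initiation"))
            else:
                day = detect_medication_initiation(
                    patient.fills, patient.pd_encounter_days(codes.pd_codes),
                    "levodopa", params)
                rows.append(
                    EventTime(patient.patient_id, "levodopa_initiation",
                              max(day - index, 0), True) if day is not None
                    else EventTime(patient.patient_id, "levodopa_initiation",
                                   max(end - index, 0), False))
        if "cognitive_decline_proxy" in supported:
            rows.append(detect_cognitive_decline_proxy(patient, index, codes, end))
        if "cognitive_decline_mmse" in supported and patient.scores:
            rows.append(detect_cognitive_decline_mmse(
                patient.scores, index, patient.patient_id))
        if "hy_stage3" in supported and patient.scores:
            rows.append(detect_scale_threshold(
                patient.scores, index, patient.patient_id))
        for event_name in ("depression", "falls_fractures"):
            if event_name in supported:
                rows.append(detect_adverse_event(patient, index, event_name, codes, end))

    df = pd.DataFrame(
        {
            "patient_id": [r.patient_id for r in rows],
            "event_type": [r.event_type for r in rows],
            "time_days": [r.time_from_index for r in rows],
            "observed": [r.observed for r in rows],
            "excluded_for_prior_event": [r.excluded_for_prior_event for r in rows],
        }
    )
    if df.empty:
        df["time_years"] = pd.Series(dtype=float)
        return df
    yg = df["patient_id"].map(year_granularity).fillna(False)
    years = df["time_days"] / DAYS_PER_YEAR
    # year-granularity cohorts report durations at whole-year resolution
    df["time_years"] = years.where(~yg, other=years.apply(math.floor))
    return df
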