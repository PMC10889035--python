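"""Domain record types shared by every pipeline stage.

All dates are integer days since a dataset-declared epoch (day 0), and all
intervals are half-open ``[start, end)`` unless a rule states otherwise.
Working in integer days makes the 730/180/90/30-day phenotyping rules exact
and keeps round-trips through the delimited-file schema lossless.

Research-style cohorts record the diagnosis at year granularity only; the
convention throughout the package is that year ``Y`` maps to July 1 of ``Y``
(``round((Y + 0.5) * 365.25)`` days) and durations for such patients are
reported at whole-year resolution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

__all__ = [
    "DAYS_PER_YEAR",
    "Encounter",
    "DiagnosisEvent",
    "PrescriptionFill",
    "ClinicalNote",
    "ScoreObservation",
    "PatientRecord",
    "CodeListConfig",
    "SCALES",
    "HY_GRID",
    "validate_range",
    "year_to_day",
    "day_to_year",
    "UnknownScaleError",
]

DAYS_PER_YEAR = 365.25

#: Valid values of the modified Hoehn & Yahr staging (0-5 with half steps
#: 1.5 and 2.5).  Extractor outputs outside this grid are treated as
#: extraction failures, never as data.
HY_GRID = (0.0, 1.0, 1.5, 2.0, 2.5, 3.0, 4.0, 5.0)

#: Recognised clinical rating scales and their valid ranges.
SCALES = ("HY", "MMSE", "MoCA", "UPDRS_total")

DRUG_CLASSES = ("levodopa", "other_pd_therapeutic", "cognition_medication", "other")

SEXES = ("male", "female")

POSITIONS = ("primary", "admitting", "other")

SETTINGS = ("inpatient", "outpatient")

SOURCES = ("structured", "extracted", "manual")


class UnknownScaleError(KeyError):
    """Raised when a scale name is not one of the recognised scales."""


def validate_range(scale: str, value: float) -> bool:
    """Return True iff ``value`` is admissible for the named rating scale.

    Hoehn & Yahr admits the modified grid :data:`HY_GRID`; MMSE and MoCA are
    integers 0-30; the UPDRS total score is an integer 0-199 (original
    full-scale maximum).
    """
    if scale == "HY":
        return float(value) in HY_GRID
    if scale in ("MMSE", "MoCA"):
        return float(value).is_integer() and 0 <= value <= 30
    if scale == "UPDRS_total":
        return float(value).is_integer() and 0 <= value <= 199
    raise UnknownScaleError(scale)


def year_to_day(year: int) -> int:
    """Mid-year (July 1) day for a year-granularity diagnosis."""
    return round((year + 0.5) * DAYS_PER_YEAR)


def day_to_year(day: float) -> int:
    return math.floor(day / DAYS_PER_YEAR)


@dataclass(frozen=True)
class Encounter:
    encounter_id: str
    date: int
    setting: str = "outpatient"
    specialty: str = ""


@dataclass(frozen=True)
class DiagnosisEvent:
    code: str
    date: int
    encounter_id: str | None = None
    position: str = "other"


@dataclass(frozen=True)
class PrescriptionFill:
    drug_class: str
    date: int
    days_supplied: int
    encounter_id: str | None = None

    def __post_init__(self):
        if self.days_supplied < 1:
            raise ValueError(f"days_supplied must be >= 1, got {self.days_supplied}")


@dataclass(frozen=True)
class ClinicalNote:
    note_id: str
    date: int
    text: str
    #: Embedded ground truth (synthetic datasets only; withheld from the
    #: extractor, used solely for accuracy reporting).
    truth_scores: dict[str, tuple[float, ...]] | None = None


@dataclass(frozen=True)
class ScoreObservation:
    scale: str
    value: float
    date: int
    source: str = "structured"


@dataclass
class PatientRecord:
    """One subject's longitudinal history.

    ``diagnosis_year`` is set for research-style patients whose diagnosis is
    recorded explicitly (at year granularity); real-world-style patients
    leave it unset and their index date must be phenotyped from codes.
    ``reported_therapy_start`` carries self-/staff-reported initiation days
    keyed by ``"pd_therapy"`` / ``"levodopa"`` where a cohort collects them.
    ``reported_events`` lists clinical events a survey-style cohort records
    as present without a date of occurrence.
    """

    patient_id: str
    sex: str
    birth_date: int
    education_years: int | None = None
    coverage_start: int | None = None
    coverage_end: int | None = None
    cohort_label: str | None = None
    diagnosis_year: int | None = None
    reported_therapy_start: dict[str, int] = field(default_factory=dict)
    reported_events: tuple[str, ...] = ()
    encounters: list[Encounter] = field(default_factory=list)
    diagnoses: list[DiagnosisEvent] = field(default_factory=list)
    fills: list[PrescriptionFill] = field(default_factory=list)
    notes: list[ClinicalNote] = field(default_factory=list)
    scores: list[ScoreObservation] = field(default_factory=list)

    def sort_lists(self) -> None:
        """Date-sort all event lists, ties broken by record id for
        reproducible loads."""
        self.encounters.sort(key=lambda e: (e.date, e.encounter_id))
        self.diagnoses.sort(key=lambda d: (d.date, d.code, d.encounter_id or ""))
        self.fills.sort(key=lambda f: (f.date, f.drug_class, f.days_supplied))
        self.notes.sort(key=lambda n: (n.date, n.note_id))
        self.scores.sort(key=lambda s: (s.date, s.scale, s.value))

    def inferred_coverage(self) -> tuple[int | None, int | None]:
        """Declared coverage window, falling back to first/last encounter."""
        start, end = self.coverage_start, self.coverage_end
        if (start is None or end is None) and self.encounters:
            days = [e.date for e in self.encounters]
            if start is None:
                start = min(days)
            if end is None:
                end = max(days) + 1
        return start, end

    def encounter_by_id(self, encounter_id: str | None) -> Encounter | None:
        if encounter_id is None:
            return None
        for e in self.encounters:
            if e.encounter_id == encounter_id:
                return e
        return None

    def pd_encounter_days(self, pd_codes: frozenset[str] | set[str]) -> set[int]:
        """Days on which an encounter carries a PD diagnosis code."""
        return {d.date for d in self.diagnoses if d.code in pd_codes}

    def copy(self) -> "PatientRecord":
        return replace(
            self,
            reported_therapy_start=dict(self.reported_therapy_start),
            encounters=list(self.encounters),
            diagnoses=list(self.diagnoses),
            fills=list(self.fills),
            notes=list(self.notes),
            scores=list(self.scores),
        )


# ---------------------------------------------------------------------------
# Code-list configuration


CODELIST_SCHEMA_ID = "pdprog-codelists/1"

_DEFAULT_MIMIC_CODES = {
    # The authoritative lists ship in dataset-specific configuration; the
    # defaults below are compact stand-ins per condition family so the
    # exclusion logic is exercised out of the box.
    "encephalitis": {"323.9", "G04.90"},
    "alzheimers": {"331.0", "G30.9"},
    "schizophrenia": {"295.90", "F20.9"},
    "wilsons_disease": {"275.1", "E83.01"},
    "msa_psp": {"333.0", "G23.1", "G90.3"},
}

_DEFAULT_EVENT_CODES = {
    "depression": {"296.2", "296.20", "311", "F32.9", "F33.9"},
    "falls_fractures": {"E888.9", "W19", "820.8", "S72.90", "S32.9"},
}


@dataclass
class CodeListConfig:
    """ICD code lists and drug-name maps driving the phenotyping rules.

    Defaults carry the published PD (ICD-9 332/332.0, ICD-10 G20) and mild
    cognitive impairment (ICD-9 331.83, ICD-10 G31.84) codes; mimic-condition
    and adverse-event sets are configurable stand-ins grouped by condition
    family.
    """

    pd_codes: set[str] = field(default_factory=lambda: {"332", "332.0", "G20"})
    mimic_exclusion_codes: dict[str, set[str]] = field(
        default_factory=lambda: {k: set(v) for k, v in _DEFAULT_MIMIC_CODES.items()}
    )
    cognitive_decline_codes: set[str] = field(
        default_factory=lambda: {"331.83", "G31.84"}
    )
    event_code_sets: dict[str, set[str]] = field(
        default_factory=lambda: {k: set(v) for k, v in _DEFAULT_EVENT_CODES.items()}
    )
    #: Treatments (drug classes or procedure codes) that qualify an
    #: outpatient event visit; empty set => only inpatient visits qualify.
    event_treatment_codes: dict[str, set[str]] = field(default_factory=dict)
    cognition_drug_names: list[str] = field(
        default_factory=lambda: ["donepezil", "rivastigmine", "memantine", "galantamine"]
    )
    #: (code, specialty) pair marking a neurology referral for cognitive
    #: decline.  No default: configuration-only criterion.
    neurology_referral_marker: tuple[str, str] | None = None

    def __post_init__(self):
        if not self.pd_codes:
            raise ValueError("pd_codes must be non-empty")
        all_mimic = self.all_mimic_codes()
        overlap = self.pd_codes & all_mimic
        if overlap:
            raise ValueError(f"codes in both pd_codes and mimic exclusions: {overlap}")

    def all_mimic_codes(self) -> set[str]:
        out: set[str] = set()
        for codes in self.mimic_exclusion_codes.values():
            out |= codes
        return out

    def to_file(self, path) -> None:
        """Write the code lists as a versioned YAML config."""
        import yaml

        payload = {
            "schema": CODELIST_SCHEMA_ID,
            "pd_codes": sorted(self.pd_codes),
            "mimic_exclusion_codes": {
                k: sorted(v) for k, v in sorted(self.mimic_exclusion_codes.items())
            },
            "cognitive_decline_codes": sorted(self.cognitive_decline_codes),
            "event_code_sets": {
                k: sorted(v) for k, v in sorted(self.event_code_sets.items())
            },
            "event_treatment_codes": {
                k: sorted(v) for k, v in sorted(self.event_treatment_codes.items())
            },
            "cognition_drug_names": list(self.cognition_drug_names),
            "neurology_referral_marker": (
                list(self.neurology_referral_marker)
                if self.neurology_referral_marker else None
            ),
        }
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)

    @classmethod
    def from_file(cls, path) -> "CodeListConfig":
        import yaml

        with open(path) as fh:
            payload = yaml.safe_load(fh)
        schema = payload.pop("schema", None)
        if schema != CODELIST_SCHEMA_ID:
            raise ValueError(
                f"unsupported code-list schema {schema!r}; "
                f"expected {CODELIST_SCHEMA_ID!r}"
            )
        marker = payload.pop("neurology_referral_marker", None)
        return cls(
            pd_codes=set(payload["pd_codes"]),
            mimic_exclusion_codes={
                k: set(v) for k, v in payload["mimic_exclusion_codes"].items()
            },
            cognitive_decline_codes=set(payload["cognitive_decline_codes"]),
            event_code_sets={
                k: set(v) for k, v in payload["event_code_sets"].items()
            },
            event_treatment_codes={
                k: set(v) for k, v in payload.get("event_treatment_codes", {}).items()
            },
            cognition_drug_names=list(payload["cognition_drug_names"]),
            neurology_referral_marker=tuple(marker) if marker else None,
        )
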