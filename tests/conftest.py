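"""Shared fixtures: hand-built patient records and small synthetic cohorts."""

from __future__ import annotations

import pytest

from pdprog.model import (
    CodeListConfig,
    DiagnosisEvent,
    Encounter,
    PatientRecord,
)
from pdprog.synth import default_config, generate_population


def make_patient(
    pid: str,
    index: int | None = 2000,
    coverage_start: int = 500,
    coverage_end: int = 5000,
    confirm_gap: int | None = 60,
    mimic_at: int | None = None,
    cohort_label: str = "rwd_emr",
    **kwargs,
) -> PatientRecord:
    """A real-world-style patient with configurable rule compliance.

    ``index=None`` omits PD codes entirely; ``confirm_gap=None`` omits the
    confirmation code; ``mimic_at`` plants an Alzheimer's stand-in code.
    """
    rec = PatientRecord(
        patient_id=pid,
        sex="male",
        birth_date=index - 70 * 365 if index else -20000,
        coverage_start=coverage_start,
        coverage_end=coverage_end,
        cohort_label=cohort_label,
        **kwargs,
    )
    eid = [0]

    def enc(date, setting="outpatient"):
        e = Encounter(f"{pid}-e{eid[0]}", date, setting)
        eid[0] += 1
        rec.encounters.append(e)
        return e

    enc(coverage_start)
    enc(coverage_start + 365)
    if index is not None:
        e = enc(index)
        rec.diagnoses.append(DiagnosisEvent("G20", index, e.encounter_id))
        if confirm_gap is not None:
            e2 = enc(index + confirm_gap)
            rec.diagnoses.append(DiagnosisEvent("332.0", index + confirm_gap,
                                                e2.encounter_id))
    if mimic_at is not None:
        e3 = enc(mimic_at)
        rec.diagnoses.append(DiagnosisEvent("G30.9", mimic_at, e3.encounter_id))
    rec.sort_lists()
    return rec


@pytest.fixture
def codes() -> CodeListConfig:
    return CodeListConfig()


@pytest.fixture
def attrition_fixture() -> list[PatientRecord]:
    """Twelve handcrafted patients: 2 without any PD code, 2 with too-short
    pre-index history, 2 without a confirmation code, 2 with a mimic
    diagnosis inside the quiescence window, and 4 clean."""
    patients = []
    patients += [make_patient(f"nopd-{i}", index=None) for i in range(2)]
    patients += [
        make_patient(f"shortq-{i}", index=2000, coverage_start=1500)
        for i in range(2)
    ]
    patients += [
        make_patient(f"noconf-{i}", index=2000, confirm_gap=None) for i in range(2)
    ]
    patients += [
        make_patient(f"mimic-{i}", index=2000, mimic_at=1800) for i in range(2)
    ]
    patients += [make_patient(f"clean-{i}", index=2000) for i in range(4)]
    return patients


@pytest.fixture(scope="session")
def small_population():
    """Clean four-cohort population (no rule violators, no decoys)."""
    config = default_config(n_per_cohort=80, seed=11,
                            rule_violation_fraction=0.0, prior_event_prob=0.0)
    return generate_population(config)


@pytest.fixture(scope="session")
def default_population():
    """Default study conditions at reduced size."""
    return generate_population(default_config(n_per_cohort=120, seed=7))
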