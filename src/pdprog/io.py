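"""Readers and writers for the delimited tabular dataset schema.

A dataset is a directory of comma-separated UTF-8 tables with header rows:
``patients.csv``, ``encounters.csv``, ``diagnoses.csv``, ``fills.csv``,
``notes.csv``, ``scores.csv`` plus a small ``dataset.json`` holding the
schema id, the epoch label and the synthetic flag.  ``write_dataset`` and
``read_dataset`` are exact inverses on any valid dataset, with deterministic
row order (patient id, then date, then record id) so repeated writes are
byte-identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .model import (
    ClinicalNote,
    DiagnosisEvent,
    Encounter,
    PatientRecord,
    PrescriptionFill,
    ScoreObservation,
)

__all__ = ["Dataset", "SchemaError", "IntegrityError", "read_dataset", "write_dataset"]

logger = logging.getLogger(__name__)

SCHEMA_ID = "pdprog-dataset/1"

_REQUIRED_COLUMNS = {
    "patients.csv": ["patient_id", "sex", "birth_date"],
    "encounters.csv": ["patient_id", "encounter_id", "date", "setting", "specialty"],
    "diagnoses.csv": ["patient_id", "code", "date", "encounter_id", "position"],
    "fills.csv": ["patient_id", "drug_class", "date", "days_supplied", "encounter_id"],
    "notes.csv": ["patient_id", "note_id", "date", "text"],
    "scores.csv": ["patient_id", "scale", "value", "date", "source"],
}

_OPTIONAL_PATIENT_COLUMNS = [
    "education_years",
    "coverage_start",
    "coverage_end",
    "cohort_label",
    "diagnosis_year",
    "reported_pd_therapy_start",
    "reported_levodopa_start",
    "reported_events",
]


class SchemaError(ValueError):
    """A required table or column is missing."""


class IntegrityError(ValueError):
    """The dataset violates an integrity constraint (e.g. duplicate ids)."""


@dataclass
class Dataset:
    """A loaded dataset: patient records plus dataset-level metadata."""

    patients: list[PatientRecord]
    synthetic: bool = False
    epoch: str = "day0"
    #: (patient_id, table, detail) triples for soft validation findings.
    validation: list[tuple[str, str, str]] = field(default_factory=list)

    def __iter__(self):
        return iter(self.patients)

    def __len__(self):
        return len(self.patients)

    def by_id(self) -> dict[str, PatientRecord]:
        return {p.patient_id: p for p in self.patients}

    def by_cohort(self) -> dict[str, list[PatientRecord]]:
        out: dict[str, list[PatientRecord]] = {}
        for p in self.patients:
            out.setdefault(p.cohort_label or "", []).append(p)
        return out


def _opt_int(value) -> int | None:
    if value is None or (isinstance(value, float) and pd.isna(value)) or value == "":
        return None
    return int(value)


def _read_table(path: Path, name: str) -> pd.DataFrame:
    f = path / name
    if not f.exists():
        raise SchemaError(f"missing required table {name}")
    df = pd.read_csv(f, dtype=str, keep_default_na=False)
    missing = [c for c in _REQUIRED_COLUMNS[name] if c not in df.columns]
    if missing:
        raise SchemaError(f"{name}: missing required column(s) {missing}")
    known = set(_REQUIRED_COLUMNS[name]) | {"truth_scores"}
    if name == "patients.csv":
        known |= set(_OPTIONAL_PATIENT_COLUMNS)
    unknown = [c for c in df.columns if c not in known]
    if unknown:
        logger.warning("%s: ignoring unknown column(s) %s", name, unknown)
        df = df.drop(columns=unknown)
    return df


def read_dataset(path: str | Path) -> Dataset:
    """Load a dataset directory into :class:`Dataset`.

    Raises :class:`SchemaError` for a missing table/column and
    :class:`IntegrityError` for duplicate patient ids.  Items dated outside a
    patient's coverage window load successfully but are flagged in
    ``Dataset.validation``.
    """
    path = Path(path)
    meta = {"synthetic": False, "epoch": "day0"}
    meta_file = path / "dataset.json"
    if meta_file.exists():
        meta.update(json.loads(meta_file.read_text()))

    pat = _read_table(path, "patients.csv")
    dup = pat["patient_id"][pat["patient_id"].duplicated()]
    if len(dup):
        raise IntegrityError(f"duplicate patient_id(s): {sorted(set(dup))}")

    records: dict[str, PatientRecord] = {}
    for row in pat.itertuples(index=False):
        d = row._asdict()
        rts = {}
        if _opt_int(d.get("reported_pd_therapy_start")) is not None:
            rts["pd_therapy"] = int(d["reported_pd_therapy_start"])
        if _opt_int(d.get("reported_levodopa_start")) is not None:
            rts["levodopa"] = int(d["reported_levodopa_start"])
        events = tuple(e for e in str(d.get("reported_events", "")).split(";") if e)
        records[d["patient_id"]] = PatientRecord(
            patient_id=d["patient_id"],
            sex=d["sex"],
            birth_date=int(d["birth_date"]),
            education_years=_opt_int(d.get("education_years")),
            coverage_start=_opt_int(d.get("coverage_start")),
            coverage_end=_opt_int(d.get("coverage_end")),
            cohort_label=d.get("cohort_label") or None,
            diagnosis_year=_opt_int(d.get("diagnosis_year")),
            reported_therapy_start=rts,
            reported_events=events,
        )

    def target(pid: str, table: str) -> PatientRecord:
        if pid not in records:
            raise IntegrityError(f"{table}: unknown patient_id {pid!r}")
        return records[pid]

    for row in _read_table(path, "encounters.csv").itertuples(index=False):
        target(row.patient_id, "encounters.csv").encounters.append(
            Encounter(row.encounter_id, int(row.date), row.setting, row.specialty)
        )
    for row in _read_table(path, "diagnoses.csv").itertuples(index=False):
        target(row.patient_id, "diagnoses.csv").diagnoses.append(
            DiagnosisEvent(
                row.code, int(row.date), row.encounter_id or None, row.position or "other"
            )
        )
    for row in _read_table(path, "fills.csv").itertuples(index=False):
        target(row.patient_id, "fills.csv").fills.append(
            PrescriptionFill(
                row.drug_class, int(row.date), int(row.days_supplied),
                row.encounter_id or None,
            )
        )
    notes = _read_table(path, "notes.csv")
    has_truth = "truth_scores" in notes.columns and meta["synthetic"]
    for row in notes.itertuples(index=False):
        truth = None
        if has_truth and row.truth_scores:
            truth = {
                k: tuple(float(x) for x in v)
                for k, v in json.loads(row.truth_scores).items()
            }
        target(row.patient_id, "notes.csv").notes.append(
            ClinicalNote(row.note_id, int(row.date), row.text, truth)
        )
    for row in _read_table(path, "scores.csv").itertuples(index=False):
        target(row.patient_id, "scores.csv").scores.append(
            ScoreObservation(row.scale, float(row.value), int(row.date), row.source)
        )

    validation: list[tuple[str, str, str]] = []
    for rec in records.values():
        rec.sort_lists()
        start, end = rec.inferred_coverage()
        if start is None:
            continue
        for table, items in (
            ("encounters", rec.encounters),
            ("diagnoses", rec.diagnoses),
            ("fills", rec.fills),
            ("notes", rec.notes),
            ("scores", rec.scores),
        ):
            for item in items:
                if not (start <= item.date < end):
                    validation.append(
                        (rec.patient_id, table,
                         f"date {item.date} outside coverage [{start}, {end})")
                    )

    return Dataset(
        patients=sorted(records.values(), key=lambda r: r.patient_id),
        synthetic=bool(meta["synthetic"]),
        epoch=str(meta["epoch"]),
        validation=validation,
    )


def write_dataset(
    records, path: str | Path, *, synthetic: bool = False, epoch: str = "day0"
) -> None:
    """Write records to ``path`` in the schema :func:`read_dataset` consumes.

    Row order is deterministic (patient id, date, record id); writing the
    same collection twice produces byte-identical files.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    records = sorted(records, key=lambda r: r.patient_id)

    pat_rows, enc_rows, dx_rows, fill_rows, note_rows, score_rows = [], [], [], [], [], []
    for r in records:
        pat_rows.append({
            "patient_id": r.patient_id,
            "sex": r.sex,
            "birth_date": r.birth_date,
            "education_years": "" if r.education_years is None else r.education_years,
            "coverage_start": "" if r.coverage_start is None else r.coverage_start,
            "coverage_end": "" if r.coverage_end is None else r.coverage_end,
            "cohort_label": r.cohort_label or "",
            "diagnosis_year": "" if r.diagnosis_year is None else r.diagnosis_year,
            "reported_pd_therapy_start":
                r.reported_therapy_start.get("pd_therapy", ""),
            "reported_levodopa_start": r.reported_therapy_start.get("levodopa", ""),
            "reported_events": ";".join(r.reported_events),
        })
        rec = r.copy()
        rec.sort_lists()
        for e in rec.encounters:
            enc_rows.append({"patient_id": r.patient_id, "encounter_id": e.encounter_id,
                             "date": e.date, "setting": e.setting, "specialty": e.specialty})
        for d in rec.diagnoses:
            dx_rows.append({"patient_id": r.patient_id, "code": d.code, "date": d.date,
                            "encounter_id": d.encounter_id or "", "position": d.position})
        for f in rec.fills:
            fill_rows.append({"patient_id": r.patient_id, "drug_class": f.drug_class,
                              "date": f.date, "days_supplied": f.days_supplied,
                              "encounter_id": f.encounter_id or ""})
        for n in rec.notes:
            row = {"patient_id": r.patient_id, "note_id": n.note_id, "date": n.date,
                   "text": n.text}
            if synthetic:
                row["truth_scores"] = (
                    "" if n.truth_scores is None
                    else json.dumps({k: list(v) for k, v in n.truth_scores.items()},
                                    sort_keys=True)
                )
            note_rows.append(row)
        for s in rec.scores:
            score_rows.append({"patient_id": r.patient_id, "scale": s.scale,
                               "value": s.value, "date": s.date, "source": s.source})

    def dump(name, rows, columns):
        pd.DataFrame(rows, columns=columns).to_csv(path / name, index=False)

    dump("patients.csv", pat_rows,
         _REQUIRED_COLUMNS["patients.csv"] + _OPTIONAL_PATIENT_COLUMNS)
    dump("encounters.csv", enc_rows, _REQUIRED_COLUMNS["encounters.csv"])
    dump("diagnoses.csv", dx_rows, _REQUIRED_COLUMNS["diagnoses.csv"])
    dump("fills.csv", fill_rows, _REQUIRED_COLUMNS["fills.csv"])
    note_cols = _REQUIRED_COLUMNS["notes.csv"] + (["truth_scores"] if synthetic else [])
    dump("notes.csv", note_rows, note_cols)
    dump("scores.csv", score_rows, _REQUIRED_COLUMNS["scores.csv"])
    (path / "dataset.json").write_text(
        json.dumps({"schema": SCHEMA_ID, "synthetic": synthetic, "epoch": epoch},
                   indent=2, sort_keys=True)
        + "\n"
    )
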