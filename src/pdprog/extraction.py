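"""Consensus extraction of clinical rating-scale values from note text.

A pluggable extractor (callable ``(note_text, scale, variant_id) -> value |
None``) is fanned out over prompt variants: by default 10 variants built on
score-bearing exemplars and 10 built on score-free exemplars, mirroring a
few-shot extraction setup.  A value is accepted only when at least 9 of the
10 runs in a variant set agree (and, under the default per-polarity policy,
both sets' modal values coincide); anything less is flagged for manual
review.  Accepted non-NA values must pass the scale's range check, and a
review file merges human-corrected values back in as ``source=manual``
observations.

A deterministic rule-based :func:`reference_extractor` provides the
reference backend: exact on single-mention notes, and deliberately
variant-sensitive when a note carries two distinct values for the same
scale, so genuine ambiguity produces disagreement and hence a flag.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field
from typing import Callable

import pandas as pd

from .model import ClinicalNote, ScoreObservation, validate_range

__all__ = [
    "ConsensusPolicy",
    "ConsensusResult",
    "run_consensus",
    "decide",
    "reference_extractor",
    "merge_manual_reviews",
    "extraction_accuracy_report",
]

#: Sentinel for "no score found" (the NA answer).
NA = None

Extractor = Callable[[str, str, int], float | None]

_FAILURE = "__failure__"


@dataclass(frozen=True)
class ConsensusPolicy:
    n_runs_per_polarity: int = 10
    min_agreement: int = 9
    #: "per_polarity": agreement assessed within each variant set and both
    #: modal values must coincide.  "pooled": one pooled fan-out with the
    #: threshold scaled proportionally (18 of 20 at the defaults).
    polarity: str = "per_polarity"

    def __post_init__(self):
        if not (1 <= self.min_agreement <= self.n_runs_per_polarity):
            raise ValueError("need 1 <= min_agreement <= n_runs_per_polarity")
        if self.polarity not in ("per_polarity", "pooled"):
            raise ValueError(f"unknown polarity handling {self.polarity!r}")


@dataclass
class ConsensusResult:
    note_id: str
    scale: str
    #: Outputs per variant set (one list per polarity; a single list when
    #: pooled or when built directly from one run set).
    run_outputs: list[list[object]]
    agreement_count: int
    majority_value: float | None
    decision: str          # "accepted" | "flagged"
    flag_reason: str = ""  # "", "disagreement", "tie", "out_of_range", "polarity_mismatch"

    @property
    def accepted(self) -> bool:
        return self.decision == "accepted"


def _norm_value(raw: object) -> object:
    """Normalize one run output so the agreement rule has a well-defined
    equality; unparseable outputs count as non-matching failures."""
    if raw is None:
        return NA
    if isinstance(raw, (int, float)):
        return float(raw)
    s = str(raw).strip()
    if s.upper() in ("NA", "N/A", "NONE", ""):
        return NA
    s = s.replace(",", ".")
    m = re.fullmatch(r"([IVX]+)(?:\.(\d))?", s.upper())
    if m:  # roman numeral stage, optionally with a decimal half-step
        romans = {"I": 1, "II": 2, "III": 3, "IV": 4, "V": 5}
        if m.group(1) in romans:
            v = float(romans[m.group(1)])
            if m.group(2):
                v += float("0." + m.group(2))
            return v
        return _FAILURE
    try:
        return float(s)
    except ValueError:
        return _FAILURE


def _modal(outputs: list[object]) -> tuple[object, int, bool]:
    """(modal value, multiplicity, tie?) over normalized outputs.
    Failures never become the modal value unless everything failed."""
    counts = Counter(outputs)
    non_failure = {k: v for k, v in counts.items() if k != _FAILURE}
    pool = non_failure or dict(counts)
    best = max(pool.values())
    winners = [k for k, v in pool.items() if v == best]
    tie = len(winners) > 1
    # Deterministic tie representative: NA first, then numeric order.
    winners.sort(key=lambda v: (v is not NA, v if isinstance(v, float) else 0.0))
    return winners[0], best, tie


def decide(result: ConsensusResult, policy: ConsensusPolicy) -> ConsensusResult:
    """Apply the agreement-threshold decision rule to a ConsensusResult.

    Accepted iff ``agreement_count >= min_agreement`` with an unambiguous
    modal value (both polarity sets agreeing under the per-polarity policy);
    an accepted non-NA value additionally must pass the scale's range check,
    else the note is flagged ``out_of_range``.
    """
    if result.flag_reason in ("tie", "polarity_mismatch"):
        result.decision = "flagged"
        return result
    if isinstance(result.majority_value, str):  # all runs failed to parse
        result.decision, result.flag_reason = "flagged", "disagreement"
        return result
    if result.agreement_count >= policy.min_agreement:
        if result.majority_value is not NA and not validate_range(
            result.scale, result.majority_value
        ):
            result.decision, result.flag_reason = "flagged", "out_of_range"
        else:
            result.decision, result.flag_reason = "accepted", ""
    else:
        result.decision, result.flag_reason = "flagged", "disagreement"
    return result


def consensus_from_runs(
    note_id: str,
    scale: str,
    run_sets: list[list[object]],
    policy: ConsensusPolicy,
) -> ConsensusResult:
    """Build and decide a ConsensusResult from raw run outputs."""
    norm_sets = [[_norm_value(o) for o in s] for s in run_sets]
    if policy.polarity == "pooled" and len(norm_sets) > 1:
        norm_sets = [[o for s in norm_sets for o in s]]

    modal_info = [_modal(s) for s in norm_sets]
    tie = any(t for _, _, t in modal_info)
    values = [v for v, _, _ in modal_info]
    agreement = min(c for _, c, _ in modal_info)
    if policy.polarity == "pooled":
        # one pooled fan-out; the per-set threshold scales proportionally
        total = len(norm_sets[0])
        scaled = -(-policy.min_agreement * total // policy.n_runs_per_polarity)
        res = ConsensusResult(note_id, scale, norm_sets, agreement_count=agreement,
                              majority_value=values[0], decision="flagged")
        if tie or isinstance(res.majority_value, str):
            res.flag_reason = res.flag_reason or ("tie" if tie else "disagreement")
        elif agreement < scaled:
            res.flag_reason = "disagreement"
        elif res.majority_value is not NA and not validate_range(scale, res.majority_value):
            res.flag_reason = "out_of_range"
        else:
            res.decision = "accepted"
        return res

    res = ConsensusResult(
        note_id, scale, norm_sets, agreement_count=agreement,
        majority_value=values[0], decision="flagged",
    )
    if tie:
        res.flag_reason = "tie"
    elif len(set(map(repr, values))) > 1:
        res.flag_reason = "polarity_mismatch"
    return decide(res, policy)


def run_consensus(
    note: ClinicalNote,
    scale: str,
    extractor: Extractor,
    policy: ConsensusPolicy = ConsensusPolicy(),
) -> ConsensusResult:
    """Fan an extractor out over the configured prompt variants and decide.

    Variant ids ``0..n-1`` use score-bearing exemplars and ``n..2n-1``
    score-free exemplars.  An extractor exception on one variant is recorded
    as a failure for that run and counts as non-matching.
    """
    n = policy.n_runs_per_polarity
    run_sets: list[list[object]] = []
    for polarity in (0, 1):
        outputs: list[object] = []
        for i in range(n):
            variant_id = polarity * n + i
            try:
                outputs.append(extractor(note.text, scale, variant_id))
            except Exception:
                outputs.append(_FAILURE)
        run_sets.append(outputs)
    return consensus_from_runs(note.note_id, scale, run_sets, policy)


# ---------------------------------------------------------------------------
# Deterministic reference extractor

_SCALE_PATTERNS: dict[str, list[str]] = {
    "HY": [
        r"hoehn\s*(?:&|and)\s*yahr[^0-9IVX]{0,15}([0-9]\.?[05]?)",
        r"\bh\s*[&-]?\s*y\b[^0-9IVX]{0,12}([0-9]\.?[05]?)",
        r"\bhy\s*[=:]?\s*([0-9]\.?[05]?)",
        r"hoehn\s*(?:&|and)\s*yahr[^0-9IVX]{0,15}([IVX]+(?:\.\d)?)",
        r"\bh\s*[&-]?\s*y\b[^0-9IVX]{0,12}\b([IVX]+(?:\.\d)?)\b",
    ],
    "MMSE": [
        r"mmse[^0-9]{0,15}([0-9]{1,2})\s*(?:/\s*30)?",
        r"mini[\s-]*mental[^0-9]{0,25}([0-9]{1,2})\s*(?:/\s*30)?",
    ],
    "MoCA": [
        r"moca[^0-9]{0,15}([0-9]{1,2})\s*(?:/\s*30)?",
        r"montreal\s+cognitive[^0-9]{0,25}([0-9]{1,2})\s*(?:/\s*30)?",
    ],
    "UPDRS_total": [
        r"updrs[^0-9]{0,25}([0-9]{1,3})",
        r"unified\s+parkinson[^0-9]{0,40}([0-9]{1,3})",
    ],
}


def reference_extractor(note_text: str, scale: str, variant_id: int) -> float | None:
    """Rule-based extractor over documented surface forms.

    Single match: its value.  No match: NA (None).  Multiple distinct
    matches: the value whose surface form appears first for even variant ids
    and last for odd ones — variant-sensitive by construction so multi-value
    notes disagree across the fan-out and end up flagged, the way a
    generative extractor behaves on genuinely ambiguous notes.
    """
    text = note_text.lower()
    hits: list[tuple[int, float]] = []
    for pat in _SCALE_PATTERNS[scale]:
        for m in re.finditer(pat, text, flags=re.IGNORECASE):
            val = _norm_value(m.group(1))
            if val is NA or val is _FAILURE:
                continue
            hits.append((m.start(), val))
    if not hits:
        return None
    hits.sort()
    distinct = sorted({v for _, v in hits})
    if len(distinct) == 1:
        return distinct[0]
    return hits[0][1] if variant_id % 2 == 0 else hits[-1][1]


# ---------------------------------------------------------------------------
# Manual-review merge and accuracy reporting


def extract_scores(
    notes: list[ClinicalNote],
    scale: str,
    extractor: Extractor = reference_extractor,
    policy: ConsensusPolicy = ConsensusPolicy(),
) -> list[ConsensusResult]:
    """Run consensus extraction for one scale over a note corpus."""
    return [run_consensus(n, scale, extractor, policy) for n in notes]


def merge_manual_reviews(
    results: list[ConsensusResult],
    notes_by_id: dict[str, ClinicalNote],
    review: pd.DataFrame | None = None,
) -> list[ScoreObservation]:
    """Combine accepted consensus values with human-reviewed corrections.

    ``review`` has columns (note_id, scale, value).  Reviewed values become
    ``source=manual`` observations; accepted non-NA consensus values become
    ``source=extracted``; unreviewed flagged notes contribute nothing.  A
    review row referencing a non-flagged note is ignored with a warning; a
    review value outside the scale's range is a hard error naming the row.
    """
    import logging

    flagged = {(r.note_id, r.scale) for r in results if not r.accepted}
    observations: list[ScoreObservation] = []
    for r in results:
        if r.accepted and r.majority_value is not NA:
            observations.append(
                ScoreObservation(r.scale, r.majority_value,
                                 notes_by_id[r.note_id].date, "extracted")
            )
    if review is not None:
        for i, row in enumerate(review.itertuples(index=False)):
            key = (str(row.note_id), str(row.scale))
            if key not in flagged:
                logging.getLogger(__name__).warning(
                    "review row %d references non-flagged note %s; ignored", i, key
                )
                continue
            value = float(row.value)
            if not validate_range(row.scale, value):
                raise ValueError(
                    f"review row {i} ({row.note_id}, {row.scale}): "
                    f"value {value} out of range"
                )
            observations.append(
                ScoreObservation(row.scale, value,
                                 notes_by_id[str(row.note_id)].date, "manual")
            )
    return observations


@dataclass
class AccuracyReport:
    per_scale: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def empty(self) -> bool:
        return self.per_scale.empty


def extraction_accuracy_report(
    results: list[ConsensusResult],
    notes_by_id: dict[str, ClinicalNote],
    synthetic: bool,
) -> AccuracyReport:
    """Score accepted extractions and flags against embedded ground truth.

    Per scale: accuracy of accepted extractions (value or NA) against the
    embedded truth, the flag rate, and — among flagged notes — how often the
    majority prediction was nonetheless correct.  Refuses to run when the
    dataset is not synthetic (no truth available).
    """
    if not synthetic:
        raise ValueError(
            "accuracy report requires embedded ground truth; "
            "the dataset is not flagged synthetic"
        )
    rows = []
    by_scale: dict[str, list[ConsensusResult]] = {}
    for r in results:
        by_scale.setdefault(r.scale, []).append(r)
    for scale, rs in sorted(by_scale.items()):
        n = len(rs)
        n_flagged = sum(not r.accepted for r in rs)
        correct = maj_correct = 0
        for r in rs:
            truth = (notes_by_id[r.note_id].truth_scores or {}).get(scale, ())
            truth_single = truth[0] if len(truth) == 1 else None
            if r.accepted:
                if r.majority_value is NA:
                    correct += len(truth) == 0
                else:
                    correct += truth_single is not None and r.majority_value == truth_single
            else:
                if r.majority_value is NA:
                    maj_correct += len(truth) == 0
                else:
                    maj_correct += r.majority_value in truth
        n_accepted = n - n_flagged
        rows.append({
            "scale": scale,
            "n_notes": n,
            "accepted_accuracy": correct / n_accepted if n_accepted else float("nan"),
            "flag_rate": n_flagged / n if n else float("nan"),
            "flagged_majority_correct":
                maj_correct / n_flagged if n_flagged else float("nan"),
        })
    return AccuracyReport(pd.DataFrame(rows))
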