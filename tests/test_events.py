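"""Time-to-event derivation: initiation detector (with an exhaustive
enumeration oracle), cognitive-decline definitions, threshold crossings,
adverse events, and the assembled event table."""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pytest

from pdprog.cohort import build_cohort
from pdprog.events import (
    InitiationParams,
    build_event_table,
    detect_adverse_event,
    detect_cognitive_decline_mmse,
    detect_cognitive_decline_proxy,
    detect_medication_initiation,
    detect_scale_threshold,
)
from pdprog.model import (
    CodeListConfig,
    DiagnosisEvent,
    Encounter,
    PrescriptionFill,
    ScoreObservation,
)

from conftest import make_patient


def fills_of(*specs: tuple[int, int]) -> list[PrescriptionFill]:
    return [PrescriptionFill("levodopa", d, s) for d, s in specs]


def oracle_initiation(
    fills: list[PrescriptionFill],
    pd_days: set[int],
    params: InitiationParams = InitiationParams(),
) -> int | None:
    """Independent brute force: enumerate every subset of fills as a
    candidate sequence and take the earliest qualifying first-fill date."""
    best = None
    for r in range(params.min_fills, len(fills) + 1):
        for combo in combinations(fills, r):
            first = min(f.date for f in combo)
            last = max(f.date for f in combo)
            if params.require_pd_linked_first_fill and first not in pd_days:
                continue
            if not (params.min_span_days < last - first <= params.max_span_days):
                continue
            if sum(f.days_supplied for f in combo) <= params.min_total_days:
                continue
            if best is None or first < best:
                best = first
    return best


class TestInitiationDetector:
    def test_basic_qualifying_sequence(self):
        fills = fills_of((0, 30), (40, 60), (130, 30))
        assert detect_medication_initiation(fills, {0}, "levodopa") == 0

    def test_single_ninety_day_fill_never_qualifies(self):
        assert detect_medication_initiation(fills_of((0, 90)), {0}, "levodopa") is None

    def test_skips_non_qualifying_candidate_to_later_sequence(self):
        fills = fills_of((0, 30), (200, 30), (300, 61))
        assert detect_medication_initiation(fills, {0, 200}, "levodopa") == 200

    def test_span_of_exactly_90_days_is_not_enough(self):
        fills = fills_of((0, 60), (90, 60))
        assert detect_medication_initiation(fills, {0}, "levodopa") is None

    def test_span_within_180_is_inclusive(self):
        fills = fills_of((0, 60), (180, 60))
        assert detect_medication_initiation(fills, {0}, "levodopa") == 0

    def test_first_fill_must_be_pd_linked(self):
        fills = fills_of((0, 60), (120, 60))
        assert detect_medication_initiation(fills, set(), "levodopa") is None
        assert detect_medication_initiation(fills, {0}, "levodopa") == 0

    def test_any_pd_filter_unions_drug_classes(self):
        fills = [PrescriptionFill("other_pd_therapeutic", 0, 60),
                 PrescriptionFill("levodopa", 120, 60)]
        assert detect_medication_initiation(fills, {0}, "any_pd") == 0
        assert detect_medication_initiation(fills, {0}, "levodopa") is None

    def test_matches_enumeration_oracle_on_random_histories(self):
        rng = np.random.default_rng(42)
        params = InitiationParams()
        for _ in range(300):
            n = int(rng.integers(1, 9))
            days = sorted(int(d) for d in rng.integers(0, 500, size=n))
            fills = [PrescriptionFill("levodopa", d, int(rng.integers(1, 95)))
                     for d in days]
            pd_days = {d for d in days if rng.random() < 0.6}
            assert detect_medication_initiation(fills, pd_days, "levodopa",
                                                params) == \
                oracle_initiation(fills, pd_days, params)

    def test_adding_fills_never_delays_initiation(self):
        rng = np.random.default_rng(7)
        for _ in range(200):
            n = int(rng.integers(2, 7))
            days = sorted(int(d) for d in rng.integers(0, 400, size=n))
            fills = [PrescriptionFill("levodopa", d, int(rng.integers(1, 95)))
                     for d in days]
            pd_days = set(days)
            before = detect_medication_initiation(fills, pd_days, "levodopa")
            extra_day = int(rng.integers(0, 400))
            extra = fills + [PrescriptionFill("levodopa", extra_day,
                                              int(rng.integers(1, 95)))]
            after = detect_medication_initiation(
                sorted(extra, key=lambda f: f.date), pd_days | {extra_day},
                "levodopa")
            if before is not None:
                assert after is not None and after <= before

    def test_prefix_stability_of_detected_date(self):
        fills = fills_of((0, 30), (40, 60), (130, 30), (400, 90), (500, 90))
        day = detect_medication_initiation(fills, {0, 400}, "levodopa")
        truncated = [f for f in fills if f.date <= day + 180]
        assert detect_medication_initiation(truncated, {0, 400}, "levodopa") == day


class TestCognitiveDecline:
    def test_mci_code_triggers_proxy(self, codes):
        p = make_patient("p", index=2000)
        p.diagnoses.append(DiagnosisEvent("G31.84", 2400))
        ev = detect_cognitive_decline_proxy(p, 2000, codes, follow_up_end=3000)
        assert ev.observed and ev.time_from_index == 400

    def test_cognition_medication_needs_same_day_pd_encounter(self, codes):
        p = make_patient("p", index=2000)
        p.fills.append(PrescriptionFill("cognition_medication", 2600, 30))
        ev = detect_cognitive_decline_proxy(p, 2000, codes, follow_up_end=3000)
        assert not ev.observed  # no PD code on the fill day
        p.diagnoses.append(DiagnosisEvent("G20", 2600))
        ev = detect_cognitive_decline_proxy(p, 2000, codes, follow_up_end=3000)
        assert ev.observed and ev.time_from_index == 600

    def test_nothing_qualifying_is_censored_at_follow_up_end(self, codes):
        p = make_patient("p", index=2000)
        ev = detect_cognitive_decline_proxy(p, 2000, codes, follow_up_end=2900)
        assert not ev.observed and ev.time_from_index == 900

    @pytest.mark.parametrize("values,expected_day,observed", [
        ([(2365, 26), (3095, 24)], 1095, True),
        ([(2100, 25)], 100, True),           # <= is inclusive
        ([(2100, 26), (2600, 27)], 600, False),
    ])
    def test_mmse_cutoff_definition(self, values, expected_day, observed):
        obs = [ScoreObservation("MMSE", v, d) for d, v in values]
        ev = detect_cognitive_decline_mmse(obs, 2000, "p")
        assert ev.observed is observed
        assert ev.time_from_index == expected_day

    def test_no_post_index_mmse_censors_at_index(self):
        ev = detect_cognitive_decline_mmse([], 2000, "p")
        assert not ev.observed and ev.time_from_index == 0


class TestScaleThreshold:
    def test_first_crossing_of_stage_three(self):
        obs = [ScoreObservation("HY", v, 2000 + y * 365)
               for y, v in ((1, 2.0), (3, 2.5), (5, 3.0))]
        ev = detect_scale_threshold(obs, 2000, "p")
        assert ev.observed and ev.time_from_index == 5 * 365

    def test_never_reaching_threshold_censors_at_last_observation(self):
        obs = [ScoreObservation("HY", 2.5, 2000 + y * 365) for y in (1, 2, 3)]
        ev = detect_scale_threshold(obs, 2000, "p")
        assert not ev.observed and ev.time_from_index == 3 * 365

    def test_immediate_crossing_at_first_observation(self):
        obs = [ScoreObservation("HY", 4.0, 2100)]
        ev = detect_scale_threshold(obs, 2000, "p")
        assert ev.observed and ev.time_from_index == 100


class TestAdverseEvents:
    def _patient(self, code="W19", position="primary", setting="inpatient",
                 day=2500, prior_day=None):
        p = make_patient("p", index=2000)
        enc = Encounter("ev-1", day, setting)
        p.encounters.append(enc)
        p.diagnoses.append(DiagnosisEvent(code, day, "ev-1", position))
        if prior_day is not None:
            enc2 = Encounter("ev-0", prior_day, "inpatient")
            p.encounters.append(enc2)
            p.diagnoses.append(DiagnosisEvent(code, prior_day, "ev-0", "primary"))
        p.sort_lists()
        return p

    def test_primary_inpatient_event_is_observed(self, codes):
        p = self._patient()
        ev = detect_adverse_event(p, 2000, "falls_fractures", codes, 3000)
        assert ev.observed and ev.time_from_index == 500

    def test_secondary_outpatient_code_is_censored(self, codes):
        p = self._patient(position="other", setting="outpatient")
        ev = detect_adverse_event(p, 2000, "falls_fractures", codes, 3000)
        assert not ev.observed and not ev.excluded_for_prior_event

    def test_prior_event_in_quiescence_excludes(self, codes):
        p = self._patient(code="F32.9", prior_day=1900)
        ev = detect_adverse_event(p, 2000, "depression", codes, 3000)
        assert ev.excluded_for_prior_event

    def test_outpatient_with_configured_treatment_qualifies(self):
        codes = CodeListConfig(
            event_treatment_codes={"depression": {"antidepressant"}})
        p = self._patient(code="F32.9", setting="outpatient")
        p.fills.append(PrescriptionFill("antidepressant", 2500, 30, "ev-1"))
        ev = detect_adverse_event(p, 2000, "depression", codes, 3000)
        assert ev.observed and ev.time_from_index == 500


class TestEventTable:
    def test_survey_style_has_no_levodopa_rows(self, default_population):
        records, _ = default_population
        entries, _ = build_cohort(
            [r for r in records if r.cohort_label == "research_survey"],
            mode="encounter")
        table = build_event_table(entries, {r.patient_id: r for r in records})
        assert not table.empty
        assert set(table["event_type"]) == {"pd_therapy_initiation"}

    def test_clean_cohort_recovers_true_initiation_dates_exactly(
        self, small_population
    ):
        records, truth = small_population
        recs = [r for r in records if r.cohort_label == "rwd_claims"]
        entries, _ = build_cohort(recs, mode="coverage")
        table = build_event_table(entries, {r.patient_id: r for r in recs})
        init = table[(table["event_type"] == "pd_therapy_initiation")
                     & table["observed"]]
        assert len(init) > 20
        for row in init.itertuples(index=False):
            t = truth.patients[row.patient_id]
            assert t.pd_therapy_init_day is not None
            assert row.time_days == t.pd_therapy_init_day - t.diagnosis_day
        # and no treated, emitted patient is missed
        detected = set(init["patient_id"])
        for e in entries:
            t = truth.patients[e.patient_id]
            if e.included and t.pd_therapy_init_day is not None:
                assert e.patient_id in detected

    def test_decoy_fills_do_not_shift_detected_dates(self):
        from pdprog.synth import default_config, generate_population

        config = default_config(n_per_cohort=120, seed=3,
                                rule_violation_fraction=0.0,
                                prior_event_prob=0.0)
        config.cohorts["rwd_claims"].decoy_fill_prob = 1.0
        records, truth = generate_population(config)
        recs = [r for r in records if r.cohort_label == "rwd_claims"]
        entries, _ = build_cohort(recs, mode="coverage")
        table = build_event_table(entries, {r.patient_id: r for r in recs})
        init = table[(table["event_type"] == "pd_therapy_initiation")
                     & table["observed"]]
        assert len(init) > 20
        for row in init.itertuples(index=False):
            t = truth.patients[row.patient_id]
            assert row.time_days == t.pd_therapy_init_day - t.diagnosis_day

    def test_empty_cohort_gives_empty_table(self):
        table = build_event_table([], {})
        assert table.empty

    def test_zero_event_hazards_censor_everything(self):
        from pdprog.synth import default_config, generate_population

        config = default_config(n_per_cohort=60, seed=9,
                                rule_violation_fraction=0.0,
                                prior_event_prob=0.0)
        for cc in config.cohorts.values():
            cc.hy3_hazard = cc.cognitive_decline_hazard = 0.0
            cc.depression_hazard = cc.falls_hazard = 0.0
        records, _ = generate_population(config)
        entries = []
        for label, mode in (("rwd_emr", "encounter"), ("rwd_claims", "coverage"),
                            ("research_visitbased", "encounter")):
            e, _ = build_cohort([r for r in records if r.cohort_label == label],
                                mode=mode)
            entries.extend(e)
        table = build_event_table(entries, {r.patient_id: r for r in records})
        clinical = table[~table["event_type"].isin(
            ["pd_therapy_initiation", "levodopa_initiation"])]
        assert len(clinical) > 0
        assert not clinical["observed"].any()
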