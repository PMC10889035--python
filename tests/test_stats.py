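"""Statistical layer: phi coefficient, test selection, Kaplan-Meier,
log-rank, and the progression regression with diagnostics."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from pdprog.stats import (
    ContingencyTable2x2,
    UndefinedStatisticError,
    fit_progression_model,
    km_estimate,
    levodopa_by_stage,
    log_rank,
    phi_coefficient,
    select_two_sample_test,
    validate_proxy_against_mmse,
)


def phi_via_pearson(t: ContingencyTable2x2) -> float:
    """Independent oracle: Pearson correlation of the expanded 0/1 vectors."""
    x = [1] * (t.n11 + t.n10) + [0] * (t.n01 + t.n00)
    y = [1] * t.n11 + [0] * t.n10 + [1] * t.n01 + [0] * t.n00
    return float(sps.pearsonr(x, y).statistic)


class TestPhi:
    def test_perfect_agreement(self):
        assert phi_coefficient(ContingencyTable2x2(10, 0, 0, 10)) == 1.0

    def test_independence(self):
        assert phi_coefficient(ContingencyTable2x2(5, 5, 5, 5)) == 0.0

    def test_matches_pearson_on_expanded_vectors(self):
        t = ContingencyTable2x2(40, 10, 5, 45)
        assert phi_coefficient(t) == pytest.approx(phi_via_pearson(t), abs=1e-12)

    def test_random_tables_match_pearson(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            t = ContingencyTable2x2(*(int(x) for x in rng.integers(1, 40, 4)))
            assert phi_coefficient(t) == pytest.approx(phi_via_pearson(t),
                                                       abs=1e-12)

    def test_transpose_invariance_and_row_swap_negation(self):
        t = ContingencyTable2x2(12, 3, 7, 20)
        transposed = ContingencyTable2x2(12, 7, 3, 20)
        swapped = ContingencyTable2x2(7, 20, 12, 3)
        assert phi_coefficient(t) == pytest.approx(phi_coefficient(transposed))
        assert phi_coefficient(t) == pytest.approx(-phi_coefficient(swapped))

    def test_zero_margin_is_undefined(self):
        with pytest.raises(UndefinedStatisticError):
            phi_coefficient(ContingencyTable2x2(5, 5, 0, 0))


class TestProxyValidation:
    def test_all_concordant_visits_give_phi_one(self):
        pairs = [(True, True)] * 8 + [(False, False)] * 12
        _, phi = validate_proxy_against_mmse(pairs)
        assert phi == 1.0

    def test_independent_indicators_give_phi_near_zero(self):
        rng = np.random.default_rng(4)
        pairs = [(rng.random() < 0.3, rng.random() < 0.3) for _ in range(4000)]
        _, phi = validate_proxy_against_mmse(pairs)
        assert abs(phi) < 3.0 / np.sqrt(4000)

    def test_latent_decline_generator_gives_strong_agreement(self):
        """Proxy and MMSE threshold driven by the same latent onset agree
        strongly (about a thousand visit pairs)."""
        from pdprog.cohort import build_cohort
        from pdprog.model import CodeListConfig
        from pdprog.study import _phi_pairs
        from pdprog.synth import default_config, generate_population

        config = default_config(n_per_cohort=10, seed=21,
                                rule_violation_fraction=0.0,
                                prior_event_prob=0.0)
        cc = config.cohorts["rwd_emr"]
        cc.n_patients = 350
        cc.score_in_note_prob = 1.0   # a score in every note, MMSE included
        records, _ = generate_population(config)
        recs = [r for r in records if r.cohort_label == "rwd_emr"]
        entries, _ = build_cohort(recs, mode="encounter")
        by_id = {r.patient_id: r for r in recs}
        # read embedded truth directly: the extraction stage is tested
        # elsewhere and is exact on unambiguous notes
        for r in recs:
            for note in r.notes:
                for scale, values in (note.truth_scores or {}).items():
                    if scale == "MMSE" and len(values) == 1:
                        from pdprog.model import ScoreObservation
                        r.scores.append(ScoreObservation(
                            "MMSE", values[0], note.date, "extracted"))
            r.sort_lists()
        pairs = _phi_pairs(entries, by_id, CodeListConfig())
        assert len(pairs) > 1000
        _, phi = validate_proxy_against_mmse(pairs)
        assert phi > 0.8

    def test_no_pairs_is_an_error(self):
        with pytest.raises(ValueError):
            validate_proxy_against_mmse([])


class TestTestSelection:
    def test_two_normal_samples_choose_welch(self):
        rng = np.random.default_rng(1)
        sel = select_two_sample_test(rng.normal(0, 1, 80), rng.normal(1, 2, 80))
        assert sel.chosen == "welch_t"
        assert sel.levene_p is not None
        assert sel.p_value < 0.05

    def test_skewed_sample_chooses_mann_whitney(self):
        rng = np.random.default_rng(2)
        sel = select_two_sample_test(rng.exponential(1, 80), rng.normal(0, 1, 80))
        assert sel.chosen == "mann_whitney_u"
        assert sel.levene_p is None

    def test_identical_samples_are_not_significant(self):
        rng = np.random.default_rng(3)
        a = rng.normal(0, 1, 50)
        sel = select_two_sample_test(a, a.copy())
        assert sel.p_value > 0.05

    def test_tiny_samples_rejected(self):
        with pytest.raises(ValueError):
            select_two_sample_test([1.0, 2.0], [1.0, 2.0, 3.0])

    def test_selection_is_deterministic(self):
        rng = np.random.default_rng(6)
        a, b = rng.normal(0, 1, 40), rng.normal(0.5, 1, 40)
        s1 = select_two_sample_test(a, b)
        s2 = select_two_sample_test(a, b)
        assert s1 == s2


class TestKaplanMeier:
    def test_no_censoring_closed_form(self):
        km = km_estimate([1, 2, 3, 4, 5], [True] * 5)
        assert km.median == 3
        drops = dict(zip(km.times, km.survival))
        for t, s in ((1, 0.8), (2, 0.6), (3, 0.4), (4, 0.2), (5, 0.0)):
            assert drops[t] == pytest.approx(s)

    def test_all_censored_curve_stays_at_one(self):
        km = km_estimate([2, 4, 6], [False, False, False])
        assert np.all(km.survival == 1.0)
        assert km.median is None
        assert km.median_display.startswith(">")

    def test_no_censoring_equals_empirical_survival(self):
        rng = np.random.default_rng(8)
        times = rng.exponential(5.0, 400)
        km = km_estimate(times, [True] * 400)
        for t in (1.0, 3.0, 7.0):
            assert km.survival_at(t) == pytest.approx(np.mean(times > t))

    def test_exponential_median_recovered_under_censoring(self):
        rng = np.random.default_rng(9)
        lam = 0.2
        event = rng.exponential(1 / lam, 3000)
        censor = rng.exponential(12.0, 3000)
        km = km_estimate(np.minimum(event, censor), event <= censor)
        assert km.median == pytest.approx(np.log(2) / lam, rel=0.07)

    def test_empty_input_is_an_error(self):
        with pytest.raises(ValueError):
            km_estimate([], [])


class TestLogRank:
    def test_identical_groups_give_null_result(self):
        t = [1.0, 2.0, 3.0, 4.0]
        o = [True, True, False, True]
        res = log_rank(t, o, t, o)
        assert res.statistic == pytest.approx(0.0, abs=1e-10)
        assert res.p_value == pytest.approx(1.0)

    def test_no_events_anywhere_is_defined(self):
        res = log_rank([1, 2], [False, False], [3, 4], [False, False])
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_large_hazard_ratio_detected(self):
        rng = np.random.default_rng(10)
        a = rng.exponential(1.0, 500)
        b = rng.exponential(3.0, 500)
        res = log_rank(a, [True] * 500, b, [True] * 500)
        assert res.p_value < 0.001

    def test_invariance_to_common_time_rescaling(self):
        rng = np.random.default_rng(11)
        a, b = rng.exponential(1.0, 60), rng.exponential(2.0, 60)
        oa = rng.random(60) < 0.8
        ob = rng.random(60) < 0.8
        r1 = log_rank(a, oa, b, ob)
        r2 = log_rank(a * 365.25, oa, b * 365.25, ob)
        assert r1.statistic == pytest.approx(r2.statistic, rel=1e-9)


def _progression_df(slope, intercept, n=400, noise_sd=0.0, seed=0,
                    duplicate_age=False):
    rng = np.random.default_rng(seed)
    t = rng.uniform(0, 8, n)
    age = rng.normal(65, 8, n)
    sex = np.where(rng.random(n) < 0.5, "male", "female")
    y = intercept + slope * t + rng.normal(0, noise_sd, n)
    df = pd.DataFrame({
        "scale": "UPDRS_total", "value": y, "years_since_dx": t,
        "age_at_dx": age, "sex": sex,
    })
    if duplicate_age:
        df["age_copy"] = df["age_at_dx"]
    return df


class TestProgressionModel:
    def test_noise_free_recovery_is_exact(self):
        fit = fit_progression_model(_progression_df(3.87, 18.93), "UPDRS_total")
        assert fit.slope == pytest.approx(3.87, abs=1e-8)
        assert fit.intercept == pytest.approx(18.93, abs=1e-8)
        assert fit.max_vif is not None and fit.max_vif < 10

    def test_duplicated_covariate_is_an_error_naming_columns(self):
        df = _progression_df(1.0, 5.0, duplicate_age=True)
        with pytest.raises(ValueError, match="age"):
            fit_progression_model(df, "UPDRS_total",
                                  covariates=("age_at_dx", "sex", "age_copy"))

    def test_near_duplicate_covariate_flags_high_vif(self):
        df = _progression_df(1.0, 5.0, noise_sd=1.0)
        rng = np.random.default_rng(1)
        df["age_copy"] = df["age_at_dx"] + rng.normal(0, 1e-3, len(df))
        fit = fit_progression_model(df, "UPDRS_total",
                                    covariates=("age_at_dx", "sex", "age_copy"))
        assert fit.max_vif > 10

    def test_too_few_observations_rejected(self):
        with pytest.raises(ValueError, match="10 observations"):
            fit_progression_model(_progression_df(1.0, 5.0, n=5), "UPDRS_total")

    def test_slope_ci_covers_truth_with_noise(self):
        fit = fit_progression_model(
            _progression_df(3.87, 18.93, n=2000, noise_sd=8.0, seed=3),
            "UPDRS_total")
        lo, hi = fit.slope_ci
        assert lo < 3.87 < hi


class TestLevodopaByStage:
    def test_universal_early_initiation_gives_fraction_one(self):
        init = pd.DataFrame({"patient_id": ["a", "b"], "time_days": [0, 10],
                             "observed": [True, True]})
        hy = pd.DataFrame({
            "patient_id": ["a", "a", "b"], "value": [2.0, 3.0, 2.5],
            "time_days": [100, 600, 200],
        })
        table = levodopa_by_stage(init, hy)
        assert (table["fraction_initiated"] == 1.0).all()

    def test_no_initiations_give_zero_fractions(self):
        init = pd.DataFrame({"patient_id": ["a"], "time_days": [500],
                             "observed": [False]})
        hy = pd.DataFrame({"patient_id": ["a"], "value": [2.5],
                           "time_days": [100]})
        table = levodopa_by_stage(init, hy)
        assert (table["fraction_initiated"] == 0.0).all()

    def test_generator_plateau_fraction_at_stage_2_5(self, default_population):
        """Treated fraction already on levodopa when first staged at 2.5 or
        later tracks the configured ~0.85 plateau."""
        from pdprog.cohort import build_cohort
        from pdprog.events import build_event_table

        records, _ = default_population
        recs = [r for r in records if r.cohort_label == "research_visitbased"]
        entries, _ = build_cohort(recs, mode="encounter")
        by_id = {r.patient_id: r for r in recs}
        table = build_event_table(entries, by_id)
        init = table[table["event_type"] == "levodopa_initiation"]
        hy_rows = [
            {"patient_id": e.patient_id, "value": s.value,
             "time_days": s.date - e.index_date}
            for e in entries if e.included
            for s in by_id[e.patient_id].scores
            if s.scale == "HY" and s.date >= e.index_date
        ]
        out = levodopa_by_stage(init, pd.DataFrame(hy_rows))
        late = out[out["stage"] >= 2.5]
        assert len(late) >= 1
        n = late["n_reaching"].sum()
        frac = (late["fraction_initiated"] * late["n_reaching"]).sum() / n
        assert abs(frac - 0.85) < 2.5 * np.sqrt(0.85 * 0.15 / n)
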