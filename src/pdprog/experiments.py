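"""Repeatable simulation experiments built on the generator and the
statistics layer: progression-parameter recovery and log-rank calibration.

These are the package's own verification studies: they regenerate data under
known conditions and measure how well the analysis recovers them.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .cohort import build_cohort
from .stats import fit_progression_model, log_rank
from .synth import CohortSimConfig, SimConfig, generate_population

__all__ = [
    "progression_recovery_study",
    "logrank_calibration",
    "logrank_power",
]

#: The two progression regimes compared throughout: research-style (slow)
#: and real-world-style (fast), as (updrs slope, updrs intercept,
#: mmse decline, mmse intercept, follow-up mean years).
RECOVERY_ARMS = {
    "research": dict(updrs_slope=1.54, updrs_intercept=28.25,
                     mmse_decline=0.11, mmse_intercept=28.7,
                     follow_up_mean_years=6.1),
    "rwd": dict(updrs_slope=3.87, updrs_intercept=18.93,
                mmse_decline=0.28, mmse_intercept=25.8,
                follow_up_mean_years=3.2),
}

TRUE_SLOPES = {("research", "UPDRS_total"): 1.54, ("rwd", "UPDRS_total"): 3.87,
               ("research", "MMSE"): -0.11, ("rwd", "MMSE"): -0.28}


def _arm_frame(arm: str, n: int, seed: int) -> pd.DataFrame:
    """Raw-trajectory structured-visit data for one regime arm."""
    cc = CohortSimConfig(label="research_visitbased", n_patients=n,
                         discretize_scores=False, updrs_intercept_sd=0.0,
                         mmse_intercept_sd=0.0, **RECOVERY_ARMS[arm])
    records, truth = generate_population(
        SimConfig(cohorts={"research_visitbased": cc}, seed=seed))
    entries, _ = build_cohort(records, mode="encounter")
    for e in entries:  # exact time axis from ground truth
        e.index_date = truth.patients[e.patient_id].diagnosis_day
    from .study import _progression_frame

    return _progression_frame(entries, {r.patient_id: r for r in records})


def progression_recovery_study(
    n_replicates: int = 100, n_per_arm: int = 1000, base_seed: int = 0
) -> pd.DataFrame:
    """Refit the progression model on fresh data ``n_replicates`` times.

    Returns one row per replicate x arm x scale with the fitted slope, its
    95% CI, whether the CI covers the generating value, and the two-arm
    slope-difference p-value (normal approximation on the replicate's pair
    of fits).
    """
    rows = []
    for rep in range(n_replicates):
        fits = {}
        for a_idx, arm in enumerate(("research", "rwd")):
            seed = (base_seed + 7919 * rep + 104729 * a_idx) % (2**31)
            frame = _arm_frame(arm, n_per_arm, seed)
            for scale in ("UPDRS_total", "MMSE"):
                fits[(arm, scale)] = fit_progression_model(frame, scale)
        for scale in ("UPDRS_total", "MMSE"):
            f1, f2 = fits[("research", scale)], fits[("rwd", scale)]
            z = (f2.slope - f1.slope) / np.hypot(
                f1.std_errors["years_since_dx"], f2.std_errors["years_since_dx"])
            diff_p = 2 * sps.norm.sf(abs(z))
            for arm in ("research", "rwd"):
                fit = fits[(arm, scale)]
                lo, hi = fit.slope_ci
                truth_slope = TRUE_SLOPES[(arm, scale)]
                rows.append({
                    "replicate": rep, "arm": arm, "scale": scale,
                    "slope": fit.slope, "ci_low": lo, "ci_high": hi,
                    "true_slope": truth_slope,
                    "covered": lo <= truth_slope <= hi,
                    "diff_p": diff_p,
                })
    return pd.DataFrame(rows)


def logrank_calibration(
    n_replicates: int = 1000, n_per_group: int = 200,
    hazard: float = 0.2, alpha: float = 0.05, seed: int = 0,
) -> float:
    """Type-I error of the log-rank test under identical exponential
    hazards (all events observed)."""
    rng = np.random.default_rng(seed)
    rejections = 0
    obs = [True] * n_per_group
    for _ in range(n_replicates):
        a = rng.exponential(1 / hazard, n_per_group)
        b = rng.exponential(1 / hazard, n_per_group)
        rejections += log_rank(a, obs, b, obs).p_value < alpha
    return rejections / n_replicates


def logrank_power(
    n_replicates: int = 200, n_per_group: int = 500,
    hazard_ratio: float = 3.0, alpha: float = 0.05, seed: int = 1,
) -> float:
    """Power of the log-rank test at the given hazard ratio."""
    rng = np.random.default_rng(seed)
    rejections = 0
    obs = [True] * n_per_group
    for _ in range(n_replicates):
        a = rng.exponential(1.0, n_per_group)
        b = rng.exponential(1.0 / hazard_ratio, n_per_group)
        rejections += log_rank(a, obs, b, obs).p_value < alpha
    return rejections / n_replicates
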