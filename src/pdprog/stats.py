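"""Statistical layer: agreement validation, test selection, survival
estimation and comparison, and the covariate-adjusted progression model.

Survival estimation and the log-rank test are delegated to ``lifelines``;
ordinary least squares and the variance-inflation diagnostics to
``statsmodels``; Shapiro-Wilk/Levene/Welch/Mann-Whitney to ``scipy``.  The
phi coefficient — the validation statistic for the composite cognitive-
decline proxy — is computed from the closed form on the 2x2 table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test
from scipy import stats as sps

__all__ = [
    "ContingencyTable2x2",
    "phi_coefficient",
    "validate_proxy_against_mmse",
    "TestSelection",
    "select_two_sample_test",
    "KMCurve",
    "km_estimate",
    "LogRankResult",
    "log_rank",
    "ProgressionFit",
    "fit_progression_model",
    "levodopa_by_stage",
    "UndefinedStatisticError",
]


class UndefinedStatisticError(ValueError):
    """The requested statistic is undefined for the given input."""


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts for two binary variables; rows = first variable yes/no,
    columns = second variable yes/no."""

    n11: int
    n10: int
    n01: int
    n00: int

    def __post_init__(self):
        if min(self.n11, self.n10, self.n01, self.n00) < 0:
            raise ValueError("counts must be nonnegative")
        if self.total < 1:
            raise ValueError("table must contain at least one observation")

    @property
    def total(self) -> int:
        return self.n11 + self.n10 + self.n01 + self.n00


def phi_coefficient(table: ContingencyTable2x2) -> float:
    """Phi = (n11*n00 - n10*n01) / sqrt of the product of the four margins.

    Equals the Pearson correlation of the two expanded 0/1 vectors.  A zero
    margin leaves the statistic undefined.
    """
    a, b, c, d = table.n11, table.n10, table.n01, table.n00
    margins = (a + b) * (c + d) * (a + c) * (b + d)
    if margins == 0:
        raise UndefinedStatisticError("phi undefined: a table margin is zero")
    return (a * d - b * c) / math.sqrt(margins)


def validate_proxy_against_mmse(pairs) -> tuple[ContingencyTable2x2, float]:
    """Agreement between the composite proxy and the MMSE <= 25 definition.

    ``pairs`` is an iterable of per-visit booleans ``(proxy_active,
    mmse_impaired)``.  Returns the 2x2 table and its phi coefficient.
    """
    n11 = n10 = n01 = n00 = 0
    for proxy, mmse in pairs:
        if proxy and mmse:
            n11 += 1
        elif proxy:
            n10 += 1
        elif mmse:
            n01 += 1
        else:
            n00 += 1
    if n11 + n10 + n01 + n00 == 0:
        raise ValueError("no paired visits available")
    table = ContingencyTable2x2(n11, n10, n01, n00)
    return table, phi_coefficient(table)


@dataclass(frozen=True)
class TestSelection:
    chosen: str  # "welch_t" | "mann_whitney_u"
    normality_p: tuple[float, float]
    levene_p: float | None
    statistic: float
    p_value: float
    n: tuple[int, int]


def select_two_sample_test(sample_a, sample_b, alpha: float = 0.05) -> TestSelection:
    """Normality-driven two-sample comparison.

    Shapiro-Wilk on each sample; if both fail to reject at ``alpha``,
    Levene's test is recorded and Welch's (unequal-variance) t-test gives the
    final p-value — Welch remains valid when variances happen to be equal,
    so the Levene outcome does not change the branch.  If either sample
    departs from normality, a two-sided Mann-Whitney U test is used.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise ValueError("each sample needs at least 3 observations")
    pa = sps.shapiro(a).pvalue
    pb = sps.shapiro(b).pvalue
    if pa > alpha and pb > alpha:
        levene_p = sps.levene(a, b).pvalue
        res = sps.ttest_ind(a, b, equal_var=False)
        return TestSelection("welch_t", (pa, pb), levene_p,
                             float(res.statistic), float(res.pvalue),
                             (len(a), len(b)))
    res = sps.mannwhitneyu(a, b, alternative="two-sided")
    return TestSelection("mann_whitney_u", (pa, pb), None,
                         float(res.statistic), float(res.pvalue), (len(a), len(b)))


@dataclass
class KMCurve:
    """Product-limit survival estimate for one group."""

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    #: Earliest time with survival <= 0.5; None when the curve never reaches
    #: 0.5, in which case the median is reported as "> last time".
    median: float | None
    last_time: float

    @property
    def median_display(self) -> str:
        return f"{self.median:g}" if self.median is not None else f">{self.last_time:g}"

    def survival_at(self, t: float) -> float:
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def km_estimate(times, observed) -> KMCurve:
    """Kaplan-Meier estimate with median = earliest time at which the
    survival probability drops to 0.5 or below."""
    times = np.asarray(times, dtype=float)
    observed = np.asarray(observed, dtype=bool)
    if len(times) == 0:
        raise ValueError("empty input")
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=observed)
    grid = kmf.survival_function_.index.to_numpy(dtype=float)
    surv = kmf.survival_function_.iloc[:, 0].to_numpy(dtype=float)
    at_risk = kmf.event_table["at_risk"].reindex(kmf.survival_function_.index)
    median = kmf.median_survival_time_
    return KMCurve(
        times=grid,
        survival=surv,
        at_risk=at_risk.to_numpy(dtype=float),
        median=None if not np.isfinite(median) else float(median),
        last_time=float(times.max()),
    )


@dataclass(frozen=True)
class LogRankResult:
    statistic: float
    df: int
    p_value: float


def log_rank(times_a, observed_a, times_b, observed_b) -> LogRankResult:
    """Standard unstratified two-group log-rank test (1 df)."""
    times_a = np.asarray(times_a, dtype=float)
    times_b = np.asarray(times_b, dtype=float)
    observed_a = np.asarray(observed_a, dtype=bool)
    observed_b = np.asarray(observed_b, dtype=bool)
    if len(times_a) == 0 or len(times_b) == 0:
        raise ValueError("both groups must be non-empty")
    if not observed_a.any() and not observed_b.any():
        return LogRankResult(0.0, 1, 1.0)
    res = logrank_test(times_a, times_b,
                       event_observed_A=observed_a, event_observed_B=observed_b)
    stat = float(res.test_statistic)
    p = float(res.p_value)
    if not np.isfinite(stat):
        stat, p = 0.0, 1.0
    return LogRankResult(stat, 1, p)


@dataclass
class ProgressionFit:
    """OLS progression fit of a rating-scale score on years since diagnosis
    plus covariates, with the standard diagnostics."""

    scale: str
    coefficients: dict[str, float]
    std_errors: dict[str, float]
    conf_int: dict[str, tuple[float, float]]
    n_obs: int
    residual_normality_p: float
    max_vif: float | None
    homoscedasticity_p: float
    covariates: list[str] = field(default_factory=list)

    @property
    def slope(self) -> float:
        return self.coefficients["years_since_dx"]

    @property
    def intercept(self) -> float:
        return self.coefficients["intercept"]

    @property
    def slope_ci(self) -> tuple[float, float]:
        return self.conf_int["years_since_dx"]


def fit_progression_model(
    df: pd.DataFrame,
    scale: str,
    covariates: tuple[str, ...] = ("age_at_dx", "sex"),
) -> ProgressionFit:
    """Fit ``value ~ years_since_dx + covariates`` by OLS with diagnostics.

    ``df`` needs columns ``scale``, ``value``, ``years_since_dx`` and the
    requested covariates (``sex`` is encoded male=1/female=0; an
    ``education_years`` covariate is used only where collected).  Irregular
    visit spacing is handled by using time since diagnosis as a continuous
    regressor.  Diagnostics: Shapiro-Wilk on residuals, max VIF whenever the
    design has two or more predictors (acceptance bound 10), and a
    Breusch-Pagan homoscedasticity p-value.
    """
    import statsmodels.api as sm
    from statsmodels.stats.diagnostic import het_breuschpagan
    from statsmodels.stats.outliers_influence import variance_inflation_factor

    sub = df[df["scale"] == scale].dropna(subset=["value", "years_since_dx"])
    covariates = tuple(c for c in covariates if c in sub.columns
                       and sub[c].notna().all())
    if len(sub) < 10:
        raise ValueError(f"need >= 10 observations for {scale}, got {len(sub)}")

    X = pd.DataFrame({"years_since_dx": sub["years_since_dx"].astype(float)})
    for c in covariates:
        col = (sub[c] == "male").astype(float) if c == "sex" else sub[c].astype(float)
        # center covariates so the intercept is the expected score at
        # diagnosis for a cohort-average patient
        X[c] = col - col.mean()
    Xc = sm.add_constant(X, prepend=True).rename(columns={"const": "intercept"})

    rank = np.linalg.matrix_rank(Xc.to_numpy())
    if rank < Xc.shape[1]:
        corr = X.corr().abs()
        np.fill_diagonal(corr.values, 0.0)
        pairs = [
            f"{a}~{b}" for a in corr.index for b in corr.columns
            if a < b and corr.loc[a, b] > 0.999999
        ]
        degenerate = [c for c in X.columns if X[c].nunique() <= 1]
        raise ValueError(
            "rank-deficient design; collinear columns: "
            + (", ".join(pairs + degenerate) or "undetermined")
        )

    model = sm.OLS(sub["value"].astype(float).to_numpy(), Xc.to_numpy()).fit()
    names = list(Xc.columns)
    ci = model.conf_int(alpha=0.05)

    resid = model.resid
    shapiro_p = float(sps.shapiro(resid[:5000]).pvalue) if len(resid) >= 3 else float("nan")
    max_vif = None
    if X.shape[1] >= 2:
        arr = Xc.to_numpy()
        max_vif = max(
            float(variance_inflation_factor(arr, j)) for j in range(1, arr.shape[1])
        )
    bp_p = float(het_breuschpagan(resid, Xc.to_numpy())[1])

    return ProgressionFit(
        scale=scale,
        coefficients=dict(zip(names, map(float, model.params))),
        std_errors=dict(zip(names, map(float, model.bse))),
        conf_int={n: (float(ci[j][0]), float(ci[j][1])) for j, n in enumerate(names)},
        n_obs=int(model.nobs),
        residual_normality_p=shapiro_p,
        max_vif=max_vif,
        homoscedasticity_p=bp_p,
        covariates=list(covariates),
    )


def levodopa_by_stage(
    initiation: pd.DataFrame, hy_obs: pd.DataFrame
) -> pd.DataFrame:
    """Fraction of patients already on levodopa when first observed at each
    H&Y stage, among patients reaching that stage.

    ``initiation``: columns (patient_id, time_days, observed) for
    levodopa_initiation.  ``hy_obs``: columns (patient_id, value,
    time_days) of H&Y observations timed from the index.
    """
    init_day = {
        r.patient_id: (r.time_days if r.observed else None)
        for r in initiation.itertuples(index=False)
    }
    stages = sorted(hy_obs["value"].unique())
    rows = []
    for stage in stages:
        reached = hy_obs[hy_obs["value"] >= stage]
        first_at = reached.groupby("patient_id")["time_days"].min()
        n = initiated = 0
        for pid, day in first_at.items():
            if pid not in init_day:
                continue
            n += 1
            start = init_day[pid]
            if start is not None and start <= day:
                initiated += 1
        rows.append({"stage": stage, "n_reaching": n,
                     "fraction_initiated": initiated / n if n else float("nan")})
    return pd.DataFrame(rows)
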