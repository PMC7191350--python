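"""Group comparison statistics: contingency tables, chi-square, ANOVA,
and adjusted prevalence ratios from log-binomial regression.

The comparison layer contrasts cohort enrollees with non-enrolled PLWH.
Categorical variables get cross-tabulations with column percentages and
Pearson chi-square tests; continuous measures get one-way ANOVA. The
adjusted analysis fits binomial GLMs with a log link (prevalence-ratio
scale); when the log-binomial fit fails to converge — a known fragility
of that model near the boundary — it falls back to a log-link Poisson
fit with a robust (HC1 sandwich) variance, flagged in the output. A
logistic model is available behind a flag for the odds-ratio scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm

from cohortlink.config import ConfigurationError, InputError

logger = logging.getLogger(__name__)

#: adjustment set of the prevalence-ratio models
DEFAULT_COVARIATES = (
    "gender_identity",
    "age_years",
    "race_ethnicity",
    "years_since_diagnosis",
    "transmission_risk",
)

MODEL_SUITE = {
    "model1_retained_in_care": "care_2017",
    "model2_ever_suppressed": "ever_suppressed_2011_2017",
    "model3_suppressed_last_lab": "suppressed_last_lab_2017",
    "model4_slow_suppression": "tts_over_24",
}


def round_half_up(x: float, decimals: int = 1) -> float:
    """Decimal round-half-up (the convention of published tables; numpy
    banker's rounding differs on exact halves)."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def column_percent(count: float, denominator: float, decimals: int = 1) -> float:
    """Percentage of a column denominator, rounded half-up."""
    if denominator <= 0:
        return 0.0
    return round_half_up(100.0 * count / denominator, decimals)


# ---------------------------------------------------------------------------
# Contingency tables


@dataclass
class ContingencyTable:
    variable: str
    categories: list[str]
    groups: list[str]
    counts: pd.DataFrame            # categories x groups
    column_percentages: pd.DataFrame
    statistic: Optional[float] = None
    df: Optional[int] = None
    p_value: Optional[float] = None


def chi_square(counts: np.ndarray | pd.DataFrame) -> tuple[float, int, float]:
    """Pearson chi-square test of independence on an r x c count table.

    Expected counts come from the row/column margins; the statistic is
    sum((O-E)^2 / E) with (r-1)(c-1) degrees of freedom, no continuity
    correction. Raises when a margin is degenerate (an expected cell of
    zero).
    """
    table = np.asarray(counts, dtype=float)
    if table.ndim != 2 or table.shape[0] < 2 or table.shape[1] < 2:
        raise InputError("chi-square needs at least a 2x2 table")
    row_totals = table.sum(axis=1)
    col_totals = table.sum(axis=0)
    if (row_totals == 0).any():
        raise InputError(f"degenerate row margin at rows {np.flatnonzero(row_totals == 0).tolist()}")
    if (col_totals == 0).any():
        raise InputError(f"degenerate column margin at columns {np.flatnonzero(col_totals == 0).tolist()}")
    stat, p, dof, _ = scipy.stats.chi2_contingency(table, correction=False)
    return float(stat), int(dof), float(p)


def build_table(
    data: pd.DataFrame,
    variable: str,
    group_col: str = "group",
    groups: Sequence[str] = ("cohort", "non_cohort"),
    categories: Sequence[str] | None = None,
) -> ContingencyTable:
    """Cross-tabulate one categorical variable by group.

    Column percentages are computed over non-missing values and rounded
    half-up to one decimal. Missing values are not given a row unless
    the variable defines an explicit missing category (e.g. "Not
    identified"). With an empty group or a single category the test is
    skipped with a warning.
    """
    sub = data.loc[data[variable].notna(), [variable, group_col]]
    if categories is None:
        categories = sorted(sub[variable].unique())
    counts = pd.DataFrame(0, index=list(categories), columns=list(groups), dtype=int)
    observed = sub.groupby([variable, group_col], observed=True).size()
    for (cat, grp), cnt in observed.items():
        if cat in counts.index and grp in counts.columns:
            counts.loc[cat, grp] = cnt
    col_totals = counts.sum(axis=0)
    pct = counts.copy().astype(float)
    for g in groups:
        denom = col_totals[g]
        pct[g] = [column_percent(c, denom) for c in counts[g]]

    table = ContingencyTable(
        variable=variable,
        categories=list(categories),
        groups=list(groups),
        counts=counts,
        column_percentages=pct,
    )
    if len(categories) < 2 or (col_totals == 0).any():
        logger.warning("table %r degenerate (single category or empty group); test skipped", variable)
        return table
    try:
        table.statistic, table.df, table.p_value = chi_square(counts.to_numpy())
    except InputError as exc:
        logger.warning("chi-square skipped for %r: %s", variable, exc)
    return table


def anova_continuous(groups: Sequence[Sequence[float]]) -> tuple[float, tuple[int, int], float]:
    """One-way ANOVA across groups: (F, (df_between, df_within), p)."""
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2 or any(len(a) < 2 for a in arrays):
        raise InputError("ANOVA needs >= 2 groups with >= 2 observations each")
    if all(np.var(a) == 0 for a in arrays):
        raise InputError("zero within-group variance in every group")
    stat, p = scipy.stats.f_oneway(*arrays)
    df_between = len(arrays) - 1
    df_within = sum(len(a) for a in arrays) - len(arrays)
    return float(stat), (df_between, df_within), float(p)


# ---------------------------------------------------------------------------
# Log-binomial prevalence ratios


@dataclass
class PrevalenceRatioEstimate:
    apr: Optional[float]
    ci_low: Optional[float]
    ci_high: Optional[float]
    converged: bool
    method: str  # 'log_binomial' | 'poisson_robust_fallback' | 'logistic'
    n: int = 0
    message: str = ""

    def __post_init__(self) -> None:
        if self.converged and self.apr is not None:
            assert self.ci_low <= self.apr <= self.ci_high


def _design_matrix(data: pd.DataFrame, exposure: str, covariates: Sequence[str]):
    cols = [exposure, *covariates]
    X = pd.get_dummies(data[cols], drop_first=True, dtype=float)
    exposure_cols = [c for c in X.columns if c == exposure or c.startswith(f"{exposure}_")]
    if len(exposure_cols) != 1:
        raise InputError(f"exposure {exposure!r} must be binary; design columns {exposure_cols}")
    X = sm.add_constant(X, has_constant="add")
    return X, exposure_cols[0]


def fit_prevalence_ratio(
    data: pd.DataFrame,
    outcome: str,
    exposure: str,
    covariates: Sequence[str] = (),
    scale: str = "prevalence_ratio",
    alpha: float = 0.05,
) -> PrevalenceRatioEstimate:
    """Adjusted prevalence ratio for a binary exposure on a binary outcome.

    Fits a binomial GLM with log link by IRLS; the exponentiated
    exposure coefficient is the APR, with a Wald CI. Rows with missing
    outcome/exposure/covariates are dropped (complete case, logged). On
    log-binomial non-convergence (or fitted probabilities escaping
    (0, 1]) the model is refit as log-link Poisson with HC1 robust
    variance and flagged ``poisson_robust_fallback``. ``scale='odds_ratio'``
    fits logistic regression instead. Separation — e.g. an exposure
    level with zero outcome events — yields ``converged=False``.
    """
    if scale not in ("prevalence_ratio", "odds_ratio"):
        raise ConfigurationError(f"unknown scale {scale!r}")
    cols = [outcome, exposure, *covariates]
    complete = data[cols].dropna()
    dropped = len(data) - len(complete)
    if dropped:
        logger.info("complete-case analysis dropped %d of %d rows", dropped, len(data))
    y = complete[outcome].astype(float)
    if not set(np.unique(y)) <= {0.0, 1.0}:
        raise InputError(f"outcome {outcome!r} must be binary 0/1")
    X, exp_col = _design_matrix(complete, exposure, covariates)
    n = len(complete)

    # separation guard: an exposure level with zero (or all) events
    events = pd.crosstab(complete[exposure], y)
    if 1.0 not in events.columns or (events.get(1.0, 0) == 0).any():
        return PrevalenceRatioEstimate(
            None, None, None, converged=False, method="log_binomial", n=n,
            message="an exposure level has zero outcome events",
        )

    if scale == "odds_ratio":
        res = sm.GLM(y, X, family=sm.families.Binomial()).fit()
        return _wald_estimate(res, exp_col, "logistic", n, alpha)

    try:
        import warnings

        with warnings.catch_warnings():
            # the log link is intentional (prevalence-ratio scale); statsmodels
            # warns that it does not respect the binomial domain
            warnings.simplefilter("ignore")
            model = sm.GLM(y, X, family=sm.families.Binomial(link=sm.families.links.Log()))
            res = model.fit(maxiter=200, tol=1e-10)
        mu = np.asarray(res.mu)
        ok = res.converged and np.all(mu > 0) and np.all(mu <= 1.0 + 1e-10)
    except Exception as exc:  # PerfectSeparation, ValueError from invalid mu, ...
        logger.info("log-binomial fit failed (%s); using Poisson fallback", exc)
        ok = False
        res = None
    if ok:
        return _wald_estimate(res, exp_col, "log_binomial", n, alpha)

    try:
        pres = sm.GLM(y, X, family=sm.families.Poisson()).fit(cov_type="HC1", maxiter=200)
        if not pres.converged:
            raise RuntimeError("Poisson fallback did not converge")
    except Exception as exc:
        return PrevalenceRatioEstimate(
            None, None, None, converged=False, method="poisson_robust_fallback", n=n,
            message=str(exc),
        )
    return _wald_estimate(pres, exp_col, "poisson_robust_fallback", n, alpha)


def _wald_estimate(res, exp_col: str, method: str, n: int, alpha: float) -> PrevalenceRatioEstimate:
    beta = float(res.params[exp_col])
    se = float(res.bse[exp_col])
    z = scipy.stats.norm.ppf(1 - alpha / 2)
    return PrevalenceRatioEstimate(
        apr=float(np.exp(beta)),
        ci_low=float(np.exp(beta - z * se)),
        ci_high=float(np.exp(beta + z * se)),
        converged=True,
        method=method,
        n=n,
    )


def prepare_model_frame(
    indicators: pd.DataFrame,
    demographics: pd.DataFrame,
    group_assignments: pd.DataFrame,
    reference_date: str = "2017-12-31",
) -> pd.DataFrame:
    """Join indicators with demographics and derive model covariates.

    Adds ``in_cohort`` (exposure), ``age_years`` and
    ``years_since_diagnosis`` at the reference date (continuous), and
    ``tts_over_24`` (1 for the > 24-month suppression category, among
    ever-suppressed persons with a defined category).
    """
    ref = pd.Timestamp(reference_date)
    df = demographics.merge(indicators, on="person_id", how="inner")
    df = df.merge(group_assignments, on="person_id", how="inner")
    df["in_cohort"] = (df["group"] == "cohort").astype(int)
    df["age_years"] = (ref - df["birth_date"]).dt.days / 365.25
    df["years_since_diagnosis"] = (ref - df["hiv_diagnosis_date"]).dt.days / 365.25
    df["tts_over_24"] = np.where(
        df["tts_category"].isna(), np.nan, (df["tts_category"] == ">24").astype(float)
    )
    return df


def run_model_suite(
    model_frame: pd.DataFrame,
    covariates: Sequence[str] = DEFAULT_COVARIATES,
    scale: str = "prevalence_ratio",
) -> pd.DataFrame:
    """Fit the four-outcome adjusted model suite.

    Models 1-3: receipt of care, ever suppressed, suppressed at the last
    outcome-year lab (persons without an outcome-year VL drop from model
    3 as not-applicable). Model 4 restricts to ever-suppressed persons
    with a defined time-to-suppression category; its outcome is the slow
    (> 24 months) category.
    """
    rows = []
    for name, outcome in MODEL_SUITE.items():
        frame = model_frame
        if name == "model4_slow_suppression":
            frame = frame.loc[
                frame["ever_suppressed_2011_2017"].astype(bool) & frame["tts_category"].notna()
            ]
        sub = frame.loc[frame[outcome].notna()].copy()
        sub[outcome] = sub[outcome].astype(float)
        est = fit_prevalence_ratio(sub, outcome, "in_cohort", covariates, scale=scale)
        rows.append(
            {
                "model": name,
                "outcome": outcome,
                "apr": est.apr,
                "ci_low": est.ci_low,
                "ci_high": est.ci_high,
                "converged": est.converged,
                "method": est.method,
                "n": est.n,
                "message": est.message,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Simulation helper for parameter-recovery checks


def simulate_log_binomial(
    n: int,
    true_pr: float,
    rng: np.random.Generator,
    baseline: float = 0.15,
    covariate_effects: Sequence[float] = (0.2, -0.15),
) -> pd.DataFrame:
    """Draw (outcome, exposure, covariates) from a log-binomial mechanism.

    Covariates are bounded uniform(-1, 1) so that with modest effects
    the linear predictor keeps event probabilities inside (0, 1) without
    truncation. Used by parameter-recovery and null-effect simulations.
    """
    exposure = rng.integers(0, 2, size=n)
    covs = rng.uniform(-1.0, 1.0, size=(n, len(covariate_effects)))
    eta = np.log(baseline) + np.log(true_pr) * exposure + covs @ np.asarray(covariate_effects)
    p = np.exp(eta)
    if p.max() >= 1.0:
        raise ConfigurationError("log-binomial mechanism produced probabilities >= 1")
    y = (rng.random(n) < p).astype(float)
    data = {"y": y, "x": exposure.astype(float)}
    for j in range(covs.shape[1]):
        data[f"z{j}"] = covs[:, j]
    return pd.DataFrame(data)
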