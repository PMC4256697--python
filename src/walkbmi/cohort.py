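"""Quartile construction and the regression analyses.

Each walkability exposure is categorized into sample quartiles (Q1 =
lowest, Q4 = highest, Q4 the referent).  Outcomes are regressed on three
quartile indicators by ordinary least squares:

* model 1 — unadjusted;
* model 2 — + age, sex, race/ethnicity (six levels including missing);
* model 3 — model 2 + tract median household income (continuous);

change-score models additionally adjust for change in age from baseline to
follow-up.  Trend p-values refit the same covariate model with the quartile
entered as a single ordinal term coded 1-2-3-4.  Confidence intervals are
normal-theory OLS intervals (heteroskedasticity-robust variance available
behind a flag); significance is two-sided at 0.05 and no multiple-testing
correction is applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .errors import DegenerateInputError, WalkbmiError
from .exposures import EXPOSURE_COLUMNS
from .anthropometry import RACE_LEVELS

#: variable order of the correlation matrix (outcome first, then exposures)
CORRELATION_ORDER = ["outcome_z"] + EXPOSURE_COLUMNS

AGE_GROUPS = ((4.0, 10.0), (10.0, 14.0), (14.0, 19.0))


def quartile_cut(values: pd.Series) -> tuple[pd.Series, tuple[float, float, float]]:
    """Assign quartile labels 1..4 (1 = lowest) with stable tie-breaking.

    Observations are ordered by value with ties broken by index (child id),
    then split into four contiguous rank blocks of near-equal size, so the
    groups differ by at most the tie-block size.  Returns the labels (int
    Series aligned to ``values``) and the three empirical cut points.
    """
    v = values.dropna()
    if v.nunique() < 4:
        raise DegenerateInputError(
            f"need >= 4 distinct values to form quartiles (got {v.nunique()})"
        )
    order = v.sort_index(kind="mergesort").sort_values(kind="mergesort").index
    n = len(order)
    labels = pd.Series(index=values.index, dtype="float")
    bounds = [0, n // 4, n // 2, (3 * n) // 4, n]
    for q in range(4):
        labels.loc[order[bounds[q]:bounds[q + 1]]] = q + 1
    # (n+1)p quantile definition, the convention of the classic survey
    # statistics packages this pipeline emulates
    cuts = tuple(
        float(np.quantile(v, p, method="weibull")) for p in (0.25, 0.5, 0.75)
    )
    return labels.astype("Int64"), cuts


def spearman_matrix(
    rows: pd.DataFrame, columns: list[str] | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Spearman rank-correlation matrix with p-values.

    Ordering follows ``CORRELATION_ORDER`` (BMI z-score first, then the
    eight exposures).  Constant columns yield NaN entries (flagged by the
    caller via ``isna``); the diagonal is exactly 1.
    """
    columns = columns or CORRELATION_ORDER
    if len(rows) < 10:
        raise WalkbmiError("need >= 10 rows for the correlation matrix")
    data = rows[columns].astype(float)
    k = len(columns)
    rho = np.eye(k)
    pval = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            xi, xj = data.iloc[:, i], data.iloc[:, j]
            if xi.nunique() < 2 or xj.nunique() < 2:
                rho[i, j] = rho[j, i] = np.nan
                pval[i, j] = pval[j, i] = np.nan
                continue
            r, p = stats.spearmanr(xi, xj)
            rho[i, j] = rho[j, i] = r
            pval[i, j] = pval[j, i] = p
    return (
        pd.DataFrame(rho, index=columns, columns=columns),
        pd.DataFrame(pval, index=columns, columns=columns),
    )


@dataclass
class QuartileTerm:
    quartile: int
    beta: float
    ci_low: float
    ci_high: float
    p: float
    n: int


@dataclass
class RegressionResult:
    """Per-exposure, per-model quartile regression summary.

    Quartile 4 is the referent (beta fixed at 0 with a degenerate CI).
    """

    exposure: str
    model_id: int
    outcome: str
    terms: list[QuartileTerm]
    trend_p: float
    cut_points: tuple[float, float, float]
    n: int
    quartile_ranges: dict[int, tuple[float, float]] = field(default_factory=dict)

    def term(self, quartile: int) -> QuartileTerm:
        for t in self.terms:
            if t.quartile == quartile:
                return t
        raise KeyError(quartile)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "exposure": self.exposure,
                "model": self.model_id,
                "outcome": self.outcome,
                "quartile": t.quartile,
                "range_low": self.quartile_ranges.get(t.quartile, (np.nan, np.nan))[0],
                "range_high": self.quartile_ranges.get(t.quartile, (np.nan, np.nan))[1],
                "beta": t.beta,
                "ci_low": t.ci_low,
                "ci_high": t.ci_high,
                "p": t.p,
                "n": t.n,
                "trend_p": self.trend_p,
            }
            for t in self.terms
        ]
        return pd.DataFrame(rows)


def _covariate_matrix(
    rows: pd.DataFrame, model_id: int, outcome: str
) -> pd.DataFrame:
    """Adjustment covariates for the given model, dummy-coded."""
    if model_id not in (1, 2, 3):
        raise WalkbmiError("model_id must be 1, 2 or 3")
    cov = pd.DataFrame(index=rows.index)
    if model_id >= 2:
        cov["age_years"] = rows["age_years"].astype(float)
        cov["sex_female"] = (rows["sex"].astype(int) == 2).astype(float)
        race = rows["race_ethnicity"].astype(str)
        unknown = set(race.unique()) - set(RACE_LEVELS)
        if unknown:
            raise WalkbmiError(f"unknown race/ethnicity levels {sorted(unknown)}")
        for level in RACE_LEVELS[1:]:  # black is the baseline level
            cov[f"race_{level}"] = (race == level).astype(float)
        if outcome == "change":
            cov["delta_age_years"] = rows["delta_age_years"].astype(float)
    if model_id >= 3:
        cov["tract_income_usd"] = rows["tract_income_usd"].astype(float)
    return cov


def _check_rank(X: pd.DataFrame) -> None:
    # scale columns to unit norm so rank detection is insensitive to units
    A = X.to_numpy(dtype=float)
    norms = np.linalg.norm(A, axis=0)
    if (norms == 0).any():
        zero = list(X.columns[norms == 0])
        raise WalkbmiError(f"rank-deficient design matrix: zero columns {zero}")
    rank = np.linalg.matrix_rank(A / norms)
    if rank < X.shape[1]:
        corr = X.loc[:, X.std() > 0].corr().abs()
        np.fill_diagonal(corr.values, 0)
        worst = corr.stack().idxmax() if corr.size else ("?", "?")
        raise WalkbmiError(
            f"rank-deficient design matrix (rank {rank} < {X.shape[1]}); "
            f"most collinear pair: {worst}"
        )


def _outcome_column(outcome: str) -> str:
    if outcome == "cross_sectional":
        return "outcome_z"
    if outcome == "change":
        return "delta_z"
    raise WalkbmiError("outcome must be 'cross_sectional' or 'change'")


def fit_quartile_model(
    rows: pd.DataFrame,
    exposure: str,
    model_id: int,
    outcome: str = "cross_sectional",
    robust: bool = False,
) -> RegressionResult:
    """OLS of the outcome on three quartile indicators (Q4 referent).

    ``rows`` must carry a ``{exposure}_q`` quartile label column (from
    :func:`quartile_cut`) or the raw exposure column, in which case the
    quartiles are computed on the fly.  Returns betas with normal-theory
    95% CIs and two-sided p-values per indicator, plus the ordinal trend
    p-value from :func:`trend_test`.
    """
    ycol = _outcome_column(outcome)
    qcol = f"{exposure}_q"
    rows = rows.copy()
    if qcol not in rows.columns:
        rows[qcol], cuts = quartile_cut(rows[exposure])
    else:
        cuts = (
            tuple(
                float(np.quantile(rows[exposure], p, method="weibull"))
                for p in (0.25, 0.5, 0.75)
            )
            if exposure in rows.columns
            else (np.nan, np.nan, np.nan)
        )
    q = rows[qcol].astype(int)
    X = pd.DataFrame(index=rows.index)
    for qq in (1, 2, 3):
        X[f"q{qq}"] = (q == qq).astype(float)
    X = pd.concat([X, _covariate_matrix(rows, model_id, outcome)], axis=1)
    X = sm.add_constant(X)
    _check_rank(X)
    y = rows[ycol].astype(float)
    fit = sm.OLS(y, X).fit(cov_type="HC1" if robust else "nonrobust")
    ci = fit.conf_int(alpha=0.05)
    terms = []
    for qq in (1, 2, 3):
        name = f"q{qq}"
        terms.append(
            QuartileTerm(
                quartile=qq,
                beta=float(fit.params[name]),
                ci_low=float(ci.loc[name, 0]),
                ci_high=float(ci.loc[name, 1]),
                p=float(fit.pvalues[name]),
                n=int((q == qq).sum()),
            )
        )
    terms.append(QuartileTerm(4, 0.0, 0.0, 0.0, np.nan, int((q == 4).sum())))
    ranges = {}
    if exposure in rows.columns:
        for qq in (1, 2, 3, 4):
            vals = rows.loc[q == qq, exposure]
            if len(vals):
                ranges[qq] = (float(vals.min()), float(vals.max()))
    tp = trend_test(rows, exposure, model_id, outcome, robust=robust)
    return RegressionResult(
        exposure=exposure, model_id=model_id, outcome=outcome, terms=terms,
        trend_p=tp, cut_points=cuts, n=len(rows), quartile_ranges=ranges,
    )


def trend_test(
    rows: pd.DataFrame,
    exposure: str,
    model_id: int,
    outcome: str = "cross_sectional",
    robust: bool = False,
) -> float:
    """Trend p-value across quartiles: the quartile entered as one ordinal
    term coded 1-2-3-4 in the same covariate model."""
    ycol = _outcome_column(outcome)
    qcol = f"{exposure}_q"
    rows = rows.copy()
    if qcol not in rows.columns:
        rows[qcol], _ = quartile_cut(rows[exposure])
    X = pd.DataFrame(index=rows.index)
    X["q_ordinal"] = rows[qcol].astype(float)
    X = pd.concat([X, _covariate_matrix(rows, model_id, outcome)], axis=1)
    X = sm.add_constant(X)
    _check_rank(X)
    fit = sm.OLS(rows[ycol].astype(float), X).fit(
        cov_type="HC1" if robust else "nonrobust"
    )
    return float(fit.pvalues["q_ordinal"])


def interaction_test(
    rows: pd.DataFrame,
    exposure: str,
    modifier: str,
    model_id: int = 3,
    outcome: str = "cross_sectional",
) -> float:
    """Wald p-value for effect modification.

    Adds ordinal-quartile x modifier product terms to the covariate model
    and jointly tests them (modifier dummy-coded when categorical).
    Reported for context only; the aggregate models remain primary.
    """
    ycol = _outcome_column(outcome)
    rows = rows.copy()
    qcol = f"{exposure}_q"
    if qcol not in rows.columns:
        rows[qcol], _ = quartile_cut(rows[exposure])
    X = pd.DataFrame(index=rows.index)
    X["q_ordinal"] = rows[qcol].astype(float)
    mod = rows[modifier]
    if mod.dtype == object or str(mod.dtype) == "category":
        levels = sorted(mod.astype(str).unique())[1:]
        mcols = []
        for lv in levels:
            c = f"mod_{lv}"
            X[c] = (mod.astype(str) == lv).astype(float)
            mcols.append(c)
    else:
        X["mod"] = mod.astype(float)
        mcols = ["mod"]
    inter = []
    for c in mcols:
        ic = f"qx_{c}"
        X[ic] = X["q_ordinal"] * X[c]
        inter.append(ic)
    X = pd.concat([X, _covariate_matrix(rows, model_id, outcome)], axis=1)
    X = X.loc[:, ~X.columns.duplicated()]
    X = X.loc[:, X.std() > 0]  # drop terms absorbed by existing covariates
    inter = [c for c in inter if c in X.columns]
    X = sm.add_constant(X)
    fit = sm.OLS(rows[ycol].astype(float), X).fit()
    wald = fit.wald_test(
        [f"{c} = 0" for c in inter], scalar=True, use_f=True
    )
    return float(wald.pvalue)


def stratified_analysis(
    rows: pd.DataFrame,
    exposure: str,
    strat: str,
    outcome: str = "cross_sectional",
    min_stratum: int = 50,
) -> dict[str, RegressionResult]:
    """Model-3 results per stratum of income quartile, age group, sex or race.

    ``strat`` is one of ``income_quartile`` (sample quartiles of tract
    income), ``age_group`` ([4,10), [10,14), [14,19) years), ``sex`` or
    ``race``.  Strata smaller than ``min_stratum`` are skipped (reported as
    absent).  Quartile labels are taken from the full sample before
    stratifying, as in a sensitivity analysis of one fitted cohort.
    """
    rows = rows.copy()
    qcol = f"{exposure}_q"
    if qcol not in rows.columns:
        rows[qcol], _ = quartile_cut(rows[exposure])
    if strat == "income_quartile":
        labels, _ = quartile_cut(rows["tract_income_usd"])
        groups = {f"income_q{q}": rows[labels == q] for q in (1, 2, 3, 4)}
    elif strat == "age_group":
        groups = {
            f"age_{lo:g}_{hi:g}": rows[(rows.age_years >= lo) & (rows.age_years < hi)]
            for lo, hi in AGE_GROUPS
        }
    elif strat == "sex":
        groups = {
            "male": rows[rows.sex.astype(int) == 1],
            "female": rows[rows.sex.astype(int) == 2],
        }
    elif strat == "race":
        groups = {
            str(lv): rows[rows.race_ethnicity.astype(str) == str(lv)]
            for lv in rows.race_ethnicity.unique()
        }
    else:
        raise WalkbmiError(f"unknown stratification {strat!r}")
    out: dict[str, RegressionResult] = {}
    for name, g in groups.items():
        if len(g) < min_stratum:
            continue
        model_id = 3
        g = g.copy()
        if strat == "sex":
            g = g.drop(columns=[])  # sex constant within stratum; handled below
        try:
            out[name] = _fit_stratum(g, exposure, model_id, outcome, strat)
        except WalkbmiError:
            continue
    return out


def _fit_stratum(
    g: pd.DataFrame, exposure: str, model_id: int, outcome: str, strat: str
) -> RegressionResult:
    """Model-3 fit within a stratum, dropping covariates constant there."""
    ycol = _outcome_column(outcome)
    qcol = f"{exposure}_q"
    q = g[qcol].astype(int)
    X = pd.DataFrame(index=g.index)
    for qq in (1, 2, 3):
        X[f"q{qq}"] = (q == qq).astype(float)
    cov = _covariate_matrix(g, model_id, outcome)
    cov = cov.loc[:, cov.std() > 0]
    X = pd.concat([X, cov], axis=1)
    X = sm.add_constant(X)
    _check_rank(X)
    fit = sm.OLS(g[ycol].astype(float), X).fit()
    ci = fit.conf_int()
    terms = [
        QuartileTerm(
            qq,
            float(fit.params[f"q{qq}"]),
            float(ci.loc[f"q{qq}", 0]),
            float(ci.loc[f"q{qq}", 1]),
            float(fit.pvalues[f"q{qq}"]),
            int((q == qq).sum()),
        )
        for qq in (1, 2, 3)
    ]
    terms.append(QuartileTerm(4, 0.0, 0.0, 0.0, np.nan, int((q == 4).sum())))
    Xt = X.drop(columns=[f"q{qq}" for qq in (1, 2, 3)])
    Xt["q_ordinal"] = q.astype(float)
    tfit = sm.OLS(g[ycol].astype(float), Xt).fit()
    return RegressionResult(
        exposure=exposure, model_id=model_id, outcome=outcome, terms=terms,
        trend_p=float(tfit.pvalues["q_ordinal"]),
        cut_points=(np.nan, np.nan, np.nan), n=len(g),
    )


def run_all_models(
    rows: pd.DataFrame,
    exposures: list[str] | None = None,
    outcome: str = "cross_sectional",
    robust: bool = False,
) -> pd.DataFrame:
    """Models 1-3 for every exposure; long results table.

    The returned frame mirrors the published layout: one row per exposure x
    model x quartile with beta, 95% CI, p, and the trend p-value.
    """
    exposures = exposures or EXPOSURE_COLUMNS
    frames = []
    for exp in exposures:
        for model_id in (1, 2, 3):
            res = fit_quartile_model(rows, exp, model_id, outcome, robust=robust)
            frames.append(res.to_frame())
    return pd.concat(frames, ignore_index=True)
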