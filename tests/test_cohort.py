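"""Quartiles, correlations, quartile OLS models, trend and strata."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import walkbmi as w
from walkbmi.cohort import _covariate_matrix
from walkbmi.errors import DegenerateInputError, WalkbmiError


def synthetic_rows(n=2000, seed=0, beta=(0.0, 0.0, 0.0), income_beta=0.0,
                   outcome_sd=1.0):
    """Analysis rows with a known quartile effect on one exposure."""
    rng = np.random.default_rng(seed)
    df = pd.DataFrame(
        {
            "child_id": [f"c{i}" for i in range(n)],
            "age_years": rng.uniform(4, 19, n),
            "sex": rng.choice([1, 2], n),
            "race_ethnicity": rng.choice(
                ["black", "hispanic", "asian", "white", "other", "missing"], n
            ),
            "tract_income_usd": rng.uniform(45_000, 135_000, n),
            "expo": rng.normal(0, 1, n),
        }
    )
    labels, _ = w.quartile_cut(df["expo"])
    df["expo_q"] = labels.astype(int)
    step = np.array([*beta, 0.0])
    df["outcome_z"] = (
        0.42
        + step[df["expo_q"].to_numpy() - 1]
        + income_beta * (df["tract_income_usd"] - df["tract_income_usd"].mean()) / 1e5
        + rng.normal(0, outcome_sd, n)
    )
    df["delta_age_years"] = rng.normal(3.2, 0.8, n)
    df["delta_z"] = rng.normal(0.07, 0.7, n)
    return df


class TestQuartileCut:
    def test_one_to_eight(self):
        s = pd.Series(np.arange(1.0, 9.0))
        labels, cuts = w.quartile_cut(s)
        assert list(labels) == [1, 1, 2, 2, 3, 3, 4, 4]
        assert cuts == pytest.approx((2.25, 4.5, 6.75))

    def test_all_equal_rejected(self):
        with pytest.raises(DegenerateInputError):
            w.quartile_cut(pd.Series([3.0] * 20))

    def test_heavy_ties_near_equal_groups(self):
        rng = np.random.default_rng(1)
        # 40 distinct home values shared by 25 children each
        vals = np.repeat(rng.normal(0, 1, 40), 25)
        s = pd.Series(vals, index=[f"c{i:04d}" for i in range(1000)])
        labels, _ = w.quartile_cut(s)
        sizes = labels.value_counts()
        assert sorted(sizes) == [250, 250, 250, 250]
        # rank-based oracle: group of each value block determined by rank
        order = s.sort_index().sort_values(kind="mergesort").index
        oracle = pd.Series(0, index=s.index)
        for q in range(4):
            oracle.loc[order[q * 250:(q + 1) * 250]] = q + 1
        assert (labels.astype(int) == oracle).all()

    def test_q1_is_lowest(self):
        s = pd.Series([10.0, 1.0, 5.0, 7.0, 2.0, 9.0, 3.0, 8.0])
        labels, _ = w.quartile_cut(s)
        assert labels[s.idxmin()] == 1
        assert labels[s.idxmax()] == 4


class TestSpearman:
    def test_diagonal_and_symmetry(self):
        df = synthetic_rows(200, seed=2)
        cols = ["outcome_z", "expo", "tract_income_usd", "age_years"]
        rho, p = w.spearman_matrix(df, cols)
        assert np.allclose(np.diag(rho), 1.0)
        assert np.allclose(rho.values, rho.values.T)
        assert ((rho.values >= -1) & (rho.values <= 1)).all()

    def test_monotone_transform_is_one(self):
        df = pd.DataFrame({"a": np.arange(20.0)})
        df["b"] = np.exp(df["a"])
        df["c"] = np.arange(20.0)[::-1]
        rho, _ = w.spearman_matrix(df, ["a", "b", "c"])
        assert rho.loc["a", "b"] == pytest.approx(1.0)
        assert rho.loc["a", "c"] == pytest.approx(-1.0)

    def test_hand_rank_formula(self):
        # 10 rows, no ties: rho = 1 - 6*sum(d^2)/(n*(n^2-1))
        a = pd.Series([3.1, 1.2, 5.6, 4.4, 2.0, 9.9, 8.1, 7.7, 6.0, 0.5])
        b = pd.Series([2.0, 1.1, 4.9, 6.2, 3.3, 8.8, 9.9, 5.5, 7.0, 0.1])
        d = a.rank() - b.rank()
        expected = 1 - 6 * (d**2).sum() / (10 * 99)
        df = pd.DataFrame({"a": a, "b": b})
        rho, _ = w.spearman_matrix(df, ["a", "b"])
        assert rho.loc["a", "b"] == pytest.approx(expected, abs=1e-12)

    def test_constant_column_flagged(self):
        df = pd.DataFrame({"a": np.arange(12.0), "b": np.ones(12)})
        rho, p = w.spearman_matrix(df, ["a", "b"])
        assert np.isnan(rho.loc["a", "b"])

    def test_too_few_rows_rejected(self):
        with pytest.raises(WalkbmiError):
            w.spearman_matrix(pd.DataFrame({"a": [1.0, 2.0]}), ["a"])


def normal_equations_fit(X, y):
    """Hand-coded OLS oracle: beta = (X'X)^-1 X'y."""
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    return np.linalg.solve(X.T @ X, X.T @ y)


class TestQuartileModel:
    def test_model1_matches_normal_equations(self):
        df = synthetic_rows(500, seed=3, beta=(0.3, 0.2, 0.1))
        res = w.fit_quartile_model(df, "expo", model_id=1)
        q = df["expo_q"].to_numpy()
        X = np.column_stack(
            [np.ones(len(df))] + [(q == k).astype(float) for k in (1, 2, 3)]
        )
        beta = normal_equations_fit(X, df["outcome_z"])
        for k in (1, 2, 3):
            assert res.term(k).beta == pytest.approx(beta[k], abs=1e-8)

    def test_referent_is_zero(self):
        df = synthetic_rows(400, seed=4)
        res = w.fit_quartile_model(df, "expo", model_id=3)
        assert res.term(4).beta == 0.0
        for k in (1, 2, 3):
            t = res.term(k)
            assert t.ci_low <= t.beta <= t.ci_high

    def test_recovers_injected_effect(self):
        beta = (-0.30, -0.20, -0.10)
        df = synthetic_rows(20_000, seed=5, beta=beta)
        res = w.fit_quartile_model(df, "expo", model_id=2)
        for k, b in zip((1, 2, 3), beta):
            t = res.term(k)
            se = (t.ci_high - t.ci_low) / (2 * 1.96)
            assert t.beta == pytest.approx(b, abs=3 * se)

    def test_constant_shift_changes_intercept_only(self):
        df = synthetic_rows(800, seed=6, beta=(0.2, 0.1, 0.0))
        r1 = w.fit_quartile_model(df, "expo", model_id=3)
        df2 = df.copy()
        df2["outcome_z"] = df2["outcome_z"] + 5.0
        r2 = w.fit_quartile_model(df2, "expo", model_id=3)
        for k in (1, 2, 3):
            assert r1.term(k).beta == pytest.approx(r2.term(k).beta, abs=1e-9)

    def test_income_confounding_flips_sign(self):
        # income raises the outcome and is negatively tied to the exposure
        rng = np.random.default_rng(77)
        n = 20_000
        income = rng.uniform(45_000, 135_000, n)
        expo = -income / 1e5 + rng.normal(0, 0.15, n)
        df = synthetic_rows(n, seed=7)
        df["expo"] = expo
        df["tract_income_usd"] = income
        labels, _ = w.quartile_cut(df["expo"])
        df["expo_q"] = labels.astype(int)
        step = np.array([0.10, 0.08, 0.05, 0.0])  # true positive Q1..Q3 effects
        df["outcome_z"] = (
            0.4
            + step[df["expo_q"].to_numpy() - 1]
            - 0.6 * (income - income.mean()) / 1e5
            + rng.normal(0, 1.0, n)
        )
        m1 = w.fit_quartile_model(df, "expo", model_id=1)
        m3 = w.fit_quartile_model(df, "expo", model_id=3)
        assert m1.term(1).beta < 0 < m3.term(1).beta

    def test_rank_deficient_design_rejected(self):
        df = synthetic_rows(300, seed=8)
        df["race_ethnicity"] = "white"  # all race dummies zero except one
        df["sex"] = 1
        df["age_years"] = 10.0  # age constant -> collinear with intercept
        with pytest.raises(WalkbmiError, match="collinear|rank"):
            w.fit_quartile_model(df, "expo", model_id=2)

    def test_change_outcome_uses_delta_age(self):
        df = synthetic_rows(3000, seed=9)
        res = w.fit_quartile_model(df, "expo", model_id=2, outcome="change")
        assert res.outcome == "change"
        cov = _covariate_matrix(df, 2, "change")
        assert "delta_age_years" in cov.columns
        assert "delta_age_years" not in _covariate_matrix(df, 2, "cross_sectional")


class TestTrend:
    def test_strong_monotone_effect_significant(self):
        df = synthetic_rows(5000, seed=10, beta=(-0.6, -0.4, -0.2))
        assert w.trend_test(df, "expo", 3) < 0.001

    def test_affine_coding_invariance(self):
        df = synthetic_rows(1000, seed=11, beta=(0.3, 0.2, 0.1))
        p_pkg = w.trend_test(df, "expo", 1)
        import statsmodels.api as sm

        X = sm.add_constant((df["expo_q"].astype(float) - 1).rename("q0"))
        p_alt = sm.OLS(df["outcome_z"], X).fit().pvalues["q0"]
        assert p_pkg == pytest.approx(p_alt, abs=1e-12)

    def test_permutation_null_uniform(self):
        df = synthetic_rows(300, seed=12)
        rng = np.random.default_rng(12)
        pvals = []
        base = df.copy()
        for _ in range(200):
            base["outcome_z"] = rng.permutation(base["outcome_z"].to_numpy())
            pvals.append(w.trend_test(base, "expo", 1))
        ks = stats.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01


class TestStratified:
    def test_partition_covers_rows(self):
        df = synthetic_rows(2000, seed=13)
        labels, _ = w.quartile_cut(df["tract_income_usd"])
        assert labels.notna().all()
        assert sorted(labels.value_counts().index) == [1, 2, 3, 4]
        assert labels.value_counts().sum() == len(df)

    def test_age_boundary_ten_goes_to_middle_group(self):
        df = synthetic_rows(400, seed=14)
        df.loc[df.index[0], "age_years"] = 10.0
        res = w.stratified_analysis(df, "expo", "age_group")
        # child 0 must be counted in the [10, 14) stratum
        mid = df[(df.age_years >= 10) & (df.age_years < 14)]
        assert df.index[0] in mid.index

    def test_income_isolated_effect_recovered(self):
        rng = np.random.default_rng(15)
        n = 12_000
        df = synthetic_rows(n, seed=15)
        inc_labels, _ = w.quartile_cut(df["tract_income_usd"])
        low = inc_labels.astype(int) <= 2
        effect = np.where(low & (df["expo_q"].astype(int) == 1), 0.35, 0.0)
        df["outcome_z"] = 0.4 + effect + rng.normal(0, 1.0, n)
        res = w.stratified_analysis(df, "expo", "income_quartile")
        assert res["income_q1"].term(1).p < 0.01
        assert res["income_q4"].term(1).p > 0.01

    def test_small_strata_skipped(self):
        df = synthetic_rows(300, seed=16)
        df["race_ethnicity"] = np.where(
            np.arange(len(df)) < 10, "other", "white"
        )
        res = w.stratified_analysis(df, "expo", "race", min_stratum=50)
        assert "other" not in res
        assert "white" in res

    def test_sex_strata(self):
        df = synthetic_rows(1200, seed=17)
        res = w.stratified_analysis(df, "expo", "sex")
        assert set(res) == {"male", "female"}
        assert res["male"].n + res["female"].n == len(df)


class TestInteraction:
    def test_returns_probability(self):
        df = synthetic_rows(1500, seed=18)
        p = w.interaction_test(df, "expo", "sex")
        assert 0.0 <= p <= 1.0

    def test_detects_strong_modification(self):
        rng = np.random.default_rng(19)
        df = synthetic_rows(8000, seed=19)
        slope = np.where(df["sex"] == 1, 0.25, -0.25)
        df["outcome_z"] = slope * df["expo_q"].astype(float) + rng.normal(0, 1, len(df))
        assert w.interaction_test(df, "expo", "sex") < 1e-4


class TestRunAllModels:
    def test_structure(self):
        df = synthetic_rows(1000, seed=20)
        df["expo2"] = df["expo"] * 2 + np.random.default_rng(20).normal(0, 0.1, len(df))
        out = w.run_all_models(df, ["expo", "expo2"])
        assert len(out) == 2 * 3 * 4  # exposures x models x quartile rows
        ref = out[(out.quartile == 4)]
        assert (ref.beta == 0).all()
        assert out.groupby(["exposure", "model"]).size().eq(4).all()
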