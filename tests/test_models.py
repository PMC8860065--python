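import numpy as np
import pandas as pd
import pytest

from phenanom.errors import DomainError, SingularFitError
from phenanom.models import (
    all_subsets,
    bh_adjust,
    contribution,
    ols_fit,
    partial_correlations,
    top_models,
    trend_with_bh,
    vif,
    window_profile,
)


def random_design(rng, n=30, p=3, names=None):
    names = names or [f"x{i}" for i in range(p)]
    X = pd.DataFrame(rng.normal(size=(n, p)), columns=names, index=range(n))
    return X


class TestOlsFit:
    def test_perfect_fit(self, rng):
        X = random_design(rng, n=20, p=2)
        y = X["x0"].copy()
        fit = ols_fit(y, X, ("x0",))
        assert fit.coefficients["x0"] == pytest.approx(1.0)
        assert fit.adj_r2 == pytest.approx(1.0)
        assert fit.rss == pytest.approx(0.0, abs=1e-20)
        assert fit.pR["x0"] == pytest.approx(1.0)

    def test_intercept_only_on_standardized_y(self, rng):
        X = random_design(rng, n=20, p=2)
        y = pd.Series(rng.normal(size=20), index=X.index)
        y = (y - y.mean()) / y.std(ddof=1)
        fit = ols_fit(y, X, ())
        assert fit.adj_r2 == pytest.approx(0.0, abs=1e-12)
        assert fit.intercept == pytest.approx(0.0, abs=1e-12)

    def test_normal_equations_oracle(self):
        # fixed 8-point toy; oracle = explicit normal-equations solve
        X = pd.DataFrame(
            {
                "a": [1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0],
                "b": [2.0, 1.0, 4.0, 3.0, 6.0, 5.0, 8.0, 7.0],
            },
            index=range(8),
        )
        y = pd.Series([1.1, 1.9, 3.2, 3.8, 5.1, 6.2, 6.8, 8.1], index=range(8))
        design = np.column_stack([np.ones(8), X["a"], X["b"]])
        beta_oracle = np.linalg.solve(design.T @ design, design.T @ y.values)
        fit = ols_fit(y, X, ("a", "b"))
        assert fit.intercept == pytest.approx(beta_oracle[0], abs=1e-10)
        assert fit.coefficients["a"] == pytest.approx(beta_oracle[1], abs=1e-10)
        assert fit.coefficients["b"] == pytest.approx(beta_oracle[2], abs=1e-10)

    def test_statsmodels_agreement(self, rng):
        import statsmodels.api as sm

        X = random_design(rng, n=25, p=3)
        y = pd.Series(
            X["x0"].values * 0.5 - X["x2"].values + rng.normal(size=25), index=X.index
        )
        fit = ols_fit(y, X, ("x0", "x1", "x2"))
        sm_fit = sm.OLS(y.values, sm.add_constant(X.values)).fit()
        assert fit.coefficients["x0"] == pytest.approx(sm_fit.params[1], abs=1e-9)
        assert fit.std_errors["x1"] == pytest.approx(sm_fit.bse[2], abs=1e-9)
        assert fit.p_values["x2"] == pytest.approx(sm_fit.pvalues[3], abs=1e-9)
        assert fit.adj_r2 == pytest.approx(sm_fit.rsquared_adj, abs=1e-9)
        assert fit.loglik == pytest.approx(sm_fit.llf, abs=1e-8)

    def test_aicc_formula(self, rng):
        X = random_design(rng, n=30, p=2)
        y = pd.Series(rng.normal(size=30), index=X.index)
        fit = ols_fit(y, X, ("x0", "x1"))
        n, k = 30, 2 + 2
        expected = -2 * fit.loglik + 2 * k + 2 * k * (k + 1) / (n - k - 1)
        assert fit.aicc == pytest.approx(expected, abs=1e-10)

    def test_rank_deficient_named(self, rng):
        X = random_design(rng, n=15, p=2)
        X["dup"] = X["x0"]
        with pytest.raises(SingularFitError):
            ols_fit(pd.Series(rng.normal(size=15), index=X.index), X, ("x0", "dup"))

    def test_sign_pr_matches_coefficient(self, rng):
        X = random_design(rng, n=40, p=3)
        y = pd.Series(
            2 * X["x0"].values - 3 * X["x1"].values + rng.normal(size=40), index=X.index
        )
        fit = ols_fit(y, X, ("x0", "x1", "x2"))
        for name in fit.predictors:
            if abs(fit.coefficients[name]) > 1e-9:
                assert np.sign(fit.pR[name]) == np.sign(fit.coefficients[name])


class TestAllSubsets:
    def test_two_candidates_four_fits(self, rng):
        X = random_design(rng, n=20, p=2)
        y = pd.Series(rng.normal(size=20), index=X.index)
        fits = all_subsets(y, X, ["x0", "x1"])
        assert len(fits) == 4
        assert fits[0].delta_aicc == 0.0

    def test_perfect_predictor_wins(self, rng):
        X = random_design(rng, n=20, p=2)
        y = X["x0"] * 2.0
        fits = all_subsets(y, X, ["x0", "x1"])
        assert fits[0].predictors == ("x0",)

    def test_exhaustive_oracle(self, rng):
        # brute-force AICc recomputation, independent of ols_fit internals
        n = 24
        X = random_design(rng, n=n, p=3)
        y = pd.Series(X["x1"].values + rng.normal(size=n), index=X.index)
        fits = all_subsets(y, X, ["x0", "x1", "x2"])
        assert len(fits) == 8

        def oracle_aicc(subset):
            design = np.column_stack(
                [np.ones(n)] + [X[c].values for c in subset]
            )
            beta, *_ = np.linalg.lstsq(design, y.values, rcond=None)
            rss = float(np.sum((y.values - design @ beta) ** 2))
            k = len(subset) + 2
            ll = -0.5 * n * (np.log(2 * np.pi) + np.log(rss / n) + 1)
            return -2 * ll + 2 * k + 2 * k * (k + 1) / (n - k - 1)

        from itertools import combinations

        ranked = sorted(
            (
                (oracle_aicc(sub), sub)
                for r in range(4)
                for sub in combinations(["x0", "x1", "x2"], r)
            )
        )
        assert [f.predictors for f in fits] == [tuple(sub) for _, sub in ranked]
        for f, (aicc, _) in zip(fits, ranked):
            assert f.aicc == pytest.approx(aicc, abs=1e-9)

    def test_refuses_large_candidate_sets(self, rng):
        X = random_design(rng, n=40, p=17)
        y = pd.Series(rng.normal(size=40), index=X.index)
        with pytest.raises(DomainError):
            all_subsets(y, X, list(X.columns))


class TestTopModelsAndContribution:
    def _fake_fits(self, deltas, predictor_lists):
        return [
            type("F", (), {"delta_aicc": d, "predictors": tuple(preds)})()
            for d, preds in zip(deltas, predictor_lists)
        ]

    def test_strict_inequality(self):
        fits = self._fake_fits([0.0, 1.5, 2.0, 3.0], [["a"], ["b"], ["c"], ["d"]])
        kept = top_models(fits, 2.0)
        assert [f.predictors for f in kept] == [("a",), ("b",)]

    def test_delta_inf_keeps_all(self):
        fits = self._fake_fits([0.0, 5.0], [["a"], ["b"]])
        assert len(top_models(fits, float("inf"))) == 2

    def test_presence_fraction(self):
        fits = self._fake_fits(
            [0, 0, 0, 0, 0], [["a"], ["a", "b"], ["a"], ["b"], ["c"]]
        )
        assert contribution("a", fits) == pytest.approx(0.6)
        assert contribution("c", fits) == pytest.approx(0.2)
        assert contribution("z", fits) == 0.0

    def test_akaike_weight_variant(self):
        fits = self._fake_fits([0.0, 2.0], [["a"], ["b"]])
        w = contribution("a", fits, method="akaike")
        expected = 1.0 / (1.0 + np.exp(-1.0))
        assert w == pytest.approx(expected)


class TestPartialCorrelations:
    def test_single_predictor_is_marginal_r(self, rng):
        X = random_design(rng, n=30, p=1, names=["x"])
        y = pd.Series(0.7 * X["x"].values + rng.normal(size=30), index=X.index)
        pr = partial_correlations(y, X, ("x",))
        marginal = np.corrcoef(y.values, X["x"].values)[0, 1]
        assert pr["x"] == pytest.approx(marginal, abs=1e-12)

    def test_two_stage_residual_oracle(self, rng):
        X = random_design(rng, n=40, p=2)
        y = pd.Series(
            X["x0"].values - 0.5 * X["x1"].values + rng.normal(size=40), index=X.index
        )
        pr = partial_correlations(y, X, ("x0", "x1"))
        # independent oracle via polynomial fits
        for target, other in (("x0", "x1"), ("x1", "x0")):
            ry = y.values - np.polyval(np.polyfit(X[other], y, 1), X[other])
            rx = X[target].values - np.polyval(
                np.polyfit(X[other], X[target], 1), X[other]
            )
            assert pr[target] == pytest.approx(np.corrcoef(ry, rx)[0, 1], abs=1e-10)

    def test_exact_dependence(self, rng):
        X = random_design(rng, n=20, p=2)
        y = X["x0"].copy()
        pr = partial_correlations(y, X, ("x0",))
        assert pr["x0"] == pytest.approx(1.0)
        # with a second predictor the control residuals of y vanish:
        # the partial correlation for x1 is undefined and must be refused
        with pytest.raises(DomainError):
            partial_correlations(y, X, ("x0", "x1"))

    def test_t_identity(self, rng):
        # pR == t / sqrt(t^2 + df) with df = n - p - 1
        n, p = 35, 4
        X = random_design(rng, n=n, p=p)
        y = pd.Series(
            X["x0"].values + 0.3 * X["x3"].values + rng.normal(size=n), index=X.index
        )
        subset = tuple(X.columns)
        fit = ols_fit(y, X, subset)
        pr = partial_correlations(y, X, subset)
        df = n - p - 1
        for name in subset:
            t = fit.t_values[name]
            assert pr[name] == pytest.approx(t / np.sqrt(t * t + df), abs=1e-9)

    def test_inverse_correlation_matrix_formulation(self, rng):
        # pR_i = -P[0, i] / sqrt(P[0,0] P[i,i]) with P = inv(corr([y, X]))
        n = 50
        X = random_design(rng, n=n, p=3)
        y = pd.Series(
            0.8 * X["x0"].values - X["x2"].values + rng.normal(size=n), index=X.index
        )
        pr = partial_correlations(y, X, tuple(X.columns))
        M = np.column_stack([y.values] + [X[c].values for c in X.columns])
        P = np.linalg.inv(np.corrcoef(M, rowvar=False))
        for i, name in enumerate(X.columns, start=1):
            expected = -P[0, i] / np.sqrt(P[0, 0] * P[i, i])
            assert pr[name] == pytest.approx(expected, abs=1e-9)


class TestVif:
    def test_single_predictor(self, rng):
        X = random_design(rng, n=20, p=1, names=["x"])
        assert vif(X, ("x",)) == {"x": 1.0}

    def test_uncorrelated_near_one(self, rng):
        X = random_design(rng, n=500, p=2)
        out = vif(X, ("x0", "x1"))
        assert out["x0"] == pytest.approx(1.0, abs=0.05)

    def test_auxiliary_regression_oracle(self, rng):
        n = 40
        x1 = rng.normal(size=n)
        X = pd.DataFrame(
            {"x1": x1, "x2": x1 + rng.normal(scale=0.05, size=n),
             "x3": rng.normal(size=n)},
            index=range(n),
        )
        out = vif(X, ("x1", "x2", "x3"))
        assert out["x1"] > 100
        # oracle: 1 / (1 - R^2) from an explicit auxiliary regression
        design = np.column_stack([np.ones(n), X["x2"], X["x3"]])
        beta, *_ = np.linalg.lstsq(design, X["x1"].values, rcond=None)
        resid = X["x1"].values - design @ beta
        r2 = 1 - resid @ resid / np.sum((X["x1"] - X["x1"].mean()) ** 2)
        assert out["x1"] == pytest.approx(1 / (1 - r2), rel=1e-6)

    def test_perfect_collinearity_is_inf(self, rng):
        x = rng.normal(size=25)
        X = pd.DataFrame({"a": x, "b": x}, index=range(25))
        out = vif(X, ("a", "b"))
        assert np.isinf(out["a"]) and np.isinf(out["b"])


class TestBH:
    def test_worked_example(self):
        adjusted = bh_adjust([0.01, 0.02, 0.04, 0.60])
        assert adjusted == pytest.approx([0.04, 0.04, 0.04 * 4 / 3, 0.60])

    def test_adjusted_at_least_raw(self, rng):
        raw = sorted(rng.uniform(size=10))
        adjusted = bh_adjust(raw)
        assert all(a >= r - 1e-12 for a, r in zip(adjusted, raw))

    def test_monotone_in_raw_order(self, rng):
        raw = list(rng.uniform(size=15))
        adjusted = bh_adjust(raw)
        pairs = sorted(zip(raw, adjusted))
        for (_, a1), (_, a2) in zip(pairs, pairs[1:]):
            assert a2 >= a1 - 1e-12

    def test_empty(self):
        assert bh_adjust([]) == []


class TestTrends:
    def test_exact_linear_series(self):
        years = range(1982, 2018)
        series = {"AA": {y: 0.1 * (y - 1982) - 1.0 for y in years}}
        (t,) = trend_with_bh(series)
        assert t.slope == pytest.approx(0.1)
        assert t.r2 == pytest.approx(1.0)
        assert t.total_shift == pytest.approx(0.1 * 35)

    def test_constant_series(self, rng):
        years = list(range(2000, 2010))
        noise = {y: 5.0 + 1e-12 * rng.normal() for y in years}
        (t,) = trend_with_bh({"flat": noise})
        assert t.slope == pytest.approx(0.0, abs=1e-9)

    def test_bh_family(self, rng):
        years = list(range(2000, 2020))
        series = {
            "a": {y: 0.5 * y + rng.normal() for y in years},
            "b": {y: rng.normal() for y in years},
            "c": {y: -0.5 * y + rng.normal() for y in years},
        }
        out = trend_with_bh(series, family=["a", "b", "c"])
        raw = [t.p_raw for t in out]
        assert [t.p_bh for t in out] == pytest.approx(bh_adjust(raw))

    def test_too_few_years(self):
        with pytest.raises(DomainError):
            trend_with_bh({"x": {2000: 1.0, 2001: 2.0}})


class TestWindowProfile:
    def test_matrix_shape_and_sign_inversion(self, rng):
        n = 40
        X = random_design(rng, n=n, p=9, names=[f"v{i}" for i in range(9)])
        X.index = range(1980, 1980 + n)
        subs = {}
        for j in range(9):
            y = -2.0 * X[f"v{j}"] + 0.2 * rng.normal(size=n)
            subs[f"SP{j + 1}"] = pd.Series(y.values, index=X.index)
        profile = window_profile(subs, X)
        assert profile.matrix.shape == (9, 9)
        assert np.all(np.abs(profile.matrix.values) <= 1 + 1e-12)
        # negative coefficients -> negative pR -> positive inverted entries
        for j in range(9):
            assert profile.matrix.loc[f"SP{j + 1}", f"v{j}"] > 0.9

    def test_null_case_entries_near_zero(self, rng):
        n = 200
        X = random_design(rng, n=n, p=3, names=["a", "b", "c"])
        X.index = range(n)
        subs = {"SP1": pd.Series(rng.normal(size=n), index=X.index)}
        profile = window_profile(subs, X)
        assert np.all(np.abs(profile.matrix.values) < 0.25)

    def test_long_table(self, rng):
        X = random_design(rng, n=30, p=2, names=["a", "b"])
        X.index = range(30)
        subs = {"SP1": pd.Series(rng.normal(size=30), index=X.index)}
        long = window_profile(subs, X).long_table()
        assert set(long.columns) == {"period", "variable", "neg_pR"}
        assert len(long) == 2
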