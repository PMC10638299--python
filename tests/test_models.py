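"""Weighted linear models: estimation, F tests, contrasts and slopes."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from dreamgraphs import (anova_term_test, associate_attributes,
                         compare_attribute, fit_weighted_lm, group_slopes,
                         pairwise_contrasts)


def frame(conds, y, x=None, w=None):
    df = pd.DataFrame({"condition": conds, "y": y})
    df["weight"] = 1.0 if w is None else w
    if x is not None:
        df["x"] = x
    return df


def wls_closed_form(X, y, w):
    W = np.diag(w)
    return np.linalg.solve(X.T @ W @ X, X.T @ W @ y)


class TestFitWeightedLm:
    def test_two_points_interpolated(self):
        df = frame(["NN"] * 2, [1.0, 3.0], x=[0.0, 1.0])
        fit = fit_weighted_lm(df, "y", covariate="x")
        assert fit.coef("Intercept") == pytest.approx(1.0)
        assert fit.coef("x") == pytest.approx(2.0)
        assert fit.wrss == pytest.approx(0.0, abs=1e-20)

    def test_textbook_least_squares(self):
        df = frame(["NN"] * 3, [0.0, 1.0, 4.0], x=[0.0, 1.0, 2.0])
        fit = fit_weighted_lm(df, "y", covariate="x")
        assert fit.coef("x") == pytest.approx(2.0)
        assert fit.coef("Intercept") == pytest.approx(-1 / 3)

    def test_weight_scale_invariance(self):
        rng = np.random.default_rng(0)
        df = frame(["NN"] * 8 + ["LL"] * 8, rng.normal(size=16),
                   x=rng.normal(size=16), w=rng.uniform(0.5, 2.0, 16))
        a = fit_weighted_lm(df, "y", covariate="x")
        df2 = df.assign(weight=df.weight * 2)
        b = fit_weighted_lm(df2, "y", covariate="x")
        assert a.params == pytest.approx(b.params, abs=1e-12)

    def test_matches_closed_form_normal_equations(self):
        rng = np.random.default_rng(7)
        n = 24
        conds = np.repeat(["NN", "LL", "OO"], n // 3)
        x = rng.normal(size=n)
        y = rng.normal(size=n)
        w = rng.uniform(0.5, 3.0, n)
        fit = fit_weighted_lm(frame(conds, y, x, w), "y", covariate="x")
        # independent design construction: NN reference, LL/OO dummies
        d_ll = (conds == "LL").astype(float)
        d_oo = (conds == "OO").astype(float)
        X = np.column_stack([np.ones(n), d_ll, d_oo, x, d_ll * x, d_oo * x])
        beta = wls_closed_form(X, y, w)
        assert fit.param_names == ["Intercept", "C[LL]", "C[OO]", "x",
                                   "C[LL]:x", "C[OO]:x"]
        assert fit.params == pytest.approx(beta, abs=1e-10)

    def test_equal_weights_reduce_to_ols(self):
        rng = np.random.default_rng(3)
        df = frame(["NN"] * 10, rng.normal(size=10), x=rng.normal(size=10))
        fit = fit_weighted_lm(df, "y", covariate="x")
        X = np.column_stack([np.ones(10), df.x])
        beta, *_ = np.linalg.lstsq(X, df.y.to_numpy(), rcond=None)
        assert fit.params == pytest.approx(beta, abs=1e-10)

    def test_rank_deficiency_detected(self):
        df = frame(["NN"] * 6, [1, 2, 3, 4, 5, 6.0], x=[1.0] * 6)
        with pytest.raises(ValueError, match="rank"):
            fit_weighted_lm(df, "y", covariate="x")

    def test_sparse_level_rejected(self):
        df = frame(["NN", "NN", "NN", "LL"], [1, 2, 3, 4.0])
        with pytest.raises(ValueError, match="LL"):
            fit_weighted_lm(df, "y")


class TestAnovaTermTest:
    def test_type_ii_equals_explicit_nested_fit(self):
        rng = np.random.default_rng(11)
        n = 18
        conds = np.repeat(["NN", "LL", "OO"], 6)
        x = rng.normal(size=n)
        y = rng.normal(size=n) + (conds == "OO") * 0.8
        w = rng.uniform(0.5, 2.0, n)
        fit = fit_weighted_lm(frame(conds, y, x, w), "y", covariate="x")
        F, dfn, dfd, P = anova_term_test(fit, "interaction")
        # two explicit WLS fits, reduced (no interaction) vs full
        d_ll = (conds == "LL").astype(float)
        d_oo = (conds == "OO").astype(float)
        Xr = np.column_stack([np.ones(n), d_ll, d_oo, x])
        Xf = np.column_stack([Xr, d_ll * x, d_oo * x])

        def wrss(X):
            b = wls_closed_form(X, y, w)
            r = y - X @ b
            return float(np.sum(w * r * r))

        F_expect = ((wrss(Xr) - wrss(Xf)) / 2) / (wrss(Xf) / (n - 6))
        assert (dfn, dfd) == (2, n - 6)
        assert F == pytest.approx(F_expect, abs=1e-10)
        assert P == pytest.approx(stats.f.sf(F_expect, 2, n - 6), abs=1e-12)

    def test_factor_tested_without_its_interaction(self):
        rng = np.random.default_rng(5)
        n = 15
        conds = np.repeat(["NN", "LL", "OO"], 5)
        df = frame(conds, rng.normal(size=n), x=rng.normal(size=n))
        fit = fit_weighted_lm(df, "y", covariate="x")
        F, dfn, dfd, _ = anova_term_test(fit, "factor", ss_type="II")
        # Type II: both models exclude the interaction -> dfd = n - 4
        assert dfd == n - 4 and dfn == 2

    def test_single_group_factor_test_errors(self):
        df = frame(["NN"] * 5, [1, 2, 3, 4, 5.0], x=[0, 1, 2, 3, 4.0])
        fit = fit_weighted_lm(df, "y", covariate="x")
        with pytest.raises(ValueError):
            anova_term_test(fit, "factor")


class TestContrastsAndSlopes:
    def test_identical_groups_null_contrast(self):
        rng = np.random.default_rng(2)
        base = rng.normal(size=8)
        df = frame(["NN"] * 8 + ["LL"] * 8, np.r_[base, base])
        fit = fit_weighted_lm(df, "y")
        ((pair, est, t, p),) = pairwise_contrasts(fit)
        assert pair == ("NN", "LL")
        assert est == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0, abs=1e-9)

    def test_three_groups_three_pairs(self):
        rng = np.random.default_rng(4)
        df = frame(np.repeat(["NN", "LL", "OO"], 5), rng.normal(size=15))
        out = pairwise_contrasts(fit_weighted_lm(df, "y"))
        assert [pair for pair, *_ in out] == [("NN", "LL"), ("NN", "OO"),
                                              ("LL", "OO")]

    def test_two_level_contrast_equals_coefficient_t(self):
        rng = np.random.default_rng(6)
        df = frame(["NN"] * 7 + ["LL"] * 7, rng.normal(size=14),
                   w=rng.uniform(0.5, 2, 14))
        fit = fit_weighted_lm(df, "y")
        ((_, est, t, p),) = pairwise_contrasts(fit)
        i = fit.param_names.index("C[LL]")
        t_coef = fit.params[i] / np.sqrt(fit.cov_params[i, i])
        assert est == pytest.approx(fit.params[i], abs=1e-12)
        assert t == pytest.approx(t_coef, abs=1e-12)

    def test_holm_and_bonferroni_never_smaller(self):
        rng = np.random.default_rng(9)
        df = frame(np.repeat(["NN", "LL", "OO"], 6), rng.normal(size=18))
        fit = fit_weighted_lm(df, "y")
        raw = [p for *_, p in pairwise_contrasts(fit, p_adjust="none")]
        for method in ("bonferroni", "holm"):
            adj = [p for *_, p in pairwise_contrasts(fit, p_adjust=method)]
            assert all(a >= r - 1e-15 for a, r in zip(adj, raw))

    def test_reference_slope_is_bare_covariate_coefficient(self):
        rng = np.random.default_rng(8)
        n = 18
        df = frame(np.repeat(["NN", "LL", "OO"], 6), rng.normal(size=n),
                   x=rng.normal(size=n))
        fit = fit_weighted_lm(df, "y", covariate="x")
        slopes = {c: s for c, s, *_ in group_slopes(fit)}
        assert slopes["NN"] == pytest.approx(fit.coef("x"), abs=1e-12)
        assert slopes["LL"] == pytest.approx(
            fit.coef("x") + fit.coef("C[LL]:x"), abs=1e-12)

    def test_slope_recovery_within_3_se(self):
        rng = np.random.default_rng(123)
        n = 30
        conds = np.repeat(["NN", "OO"], n // 2)
        x = rng.normal(size=n)
        true = {"NN": 0.5, "OO": -0.5}
        y = np.array([true[c] for c in conds]) * x + rng.normal(0, 0.3, n)
        fit = fit_weighted_lm(frame(conds, y, x), "y", covariate="x")
        for cond, slope, t, df_, p in group_slopes(fit):
            se = abs(slope / t)
            assert abs(slope - true[cond]) < 3 * se

    def test_no_interaction_fit_has_no_slopes(self):
        df = frame(["NN"] * 4, [1, 2, 3, 4.0])
        with pytest.raises(ValueError):
            group_slopes(fit_weighted_lm(df, "y"))


class TestHighLevelAnalyses:
    def test_identical_groups_give_tiny_F(self):
        base = np.arange(6.0)
        df = frame(["NN"] * 6 + ["LL"] * 6, np.r_[base, base])
        df = df.rename(columns={"y": "N"})
        res = compare_attribute(df, "N")
        assert res.F == pytest.approx(0.0, abs=1e-12)

    def test_separated_groups_rejected_reliably(self):
        rng = np.random.default_rng(42)
        hits = 0
        for _ in range(50):
            df = frame(["NN"] * 10 + ["OO"] * 10,
                       np.r_[rng.normal(10, 1, 10), rng.normal(20, 1, 10)])
            df = df.rename(columns={"y": "N"})
            if compare_attribute(df, "N").P < 0.05:
                hits += 1
        assert hits >= 50 * 0.99

    def test_condition_subsets_expressible(self):
        rng = np.random.default_rng(1)
        conds = np.repeat(["NN", "NL", "NO", "LL", "OO"], 5)
        df = frame(conds, rng.normal(size=25)).rename(columns={"y": "N"})
        typical = compare_attribute(df, "N", conditions=["NN", "LL", "OO"])
        nonlucid = compare_attribute(df, "N", conditions=["NN", "NL", "NO"])
        assert set(typical.group_means) == {"NN", "LL", "OO"}
        assert set(nonlucid.group_means) == {"NN", "NL", "NO"}

    def test_opposite_slopes_detected(self):
        rng = np.random.default_rng(77)
        hits = 0
        for _ in range(30):
            n = 30
            conds = np.repeat(["NN", "OO"], 15)
            x = rng.normal(size=n)
            y = np.where(conds == "OO", -0.5, 0.5) * x + rng.normal(0, 0.5, n)
            df = frame(conds, y, x).rename(columns={"y": "E", "x": "ASP"})
            res = associate_attributes(df, "E", "ASP")
            if res.P < 0.05:
                hits += 1
        assert hits >= 27  # >= 90% of seeds

    def test_parallel_groups_keep_null_rate(self):
        rng = np.random.default_rng(99)
        rejects = 0
        reps = 200
        for _ in range(reps):
            n = 24
            conds = np.repeat(["NN", "LL", "OO"], 8)
            x = rng.normal(size=n)
            y = 0.4 * x + rng.normal(0, 0.5, n)  # equal slopes
            res = associate_attributes(frame(conds, y, x), "y", "x")
            rejects += res.P < 0.05
        assert 0.01 <= rejects / reps <= 0.11

    def test_single_condition_reduces_to_simple_regression(self):
        rng = np.random.default_rng(10)
        df = frame(["OO"] * 12, rng.normal(size=12), x=rng.normal(size=12))
        res = associate_attributes(df, "y", "x")
        assert np.isnan(res.F)
        ((cond, slope, *_),) = res.slopes
        X = np.column_stack([np.ones(12), df.x])
        beta, *_ = np.linalg.lstsq(X, df.y.to_numpy(), rcond=None)
        assert cond == "OO" and slope == pytest.approx(beta[1], abs=1e-10)
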