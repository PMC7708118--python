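"""Tests of the statistical machinery against closed forms, independent
oracles (statsmodels, scikit-learn, scipy) and brute-force enumeration."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from condylometry.errors import RankDeficiencyError
from condylometry.morphostats import (
    bca_bootstrap_mean_ci,
    bland_altman,
    box_m,
    lda_classification_table,
    limits_of_agreement,
    pearson_screen,
    pillai_manova,
    stepwise_lda,
)
from condylometry.morphostats.bootstrap import _bca_interval


def pairs_with_moments(mean, sd):
    """Two pairs whose differences have the exact sample mean and SD."""
    half = sd * np.sqrt(2) / 2
    return [(mean + half, 0.0), (mean - half, 0.0)]


class TestBlandAltman:
    def test_identical_raters_are_all_zero(self):
        res = bland_altman([(1.0, 1.0), (2.5, 2.5), (-3.0, -3.0)])
        assert (res.mean_diff, res.sd_diff, res.loa_upper,
                res.loa_lower) == (0.0, 0.0, 0.0, 0.0)

    @pytest.mark.parametrize("mean,sd,upper,lower", [
        (-0.1, 3.8, 7.3, -7.5),
        (0.5, 0.5, 1.5, -0.5),
        (4.4, 9.7, 23.4, -14.6),
    ])
    def test_limits_match_closed_form_at_one_decimal(self, mean, sd, upper,
                                                     lower):
        res = bland_altman(pairs_with_moments(mean, sd))
        assert res.mean_diff == pytest.approx(mean, abs=1e-12)
        assert res.sd_diff == pytest.approx(sd, abs=1e-12)
        assert round(res.loa_upper, 1) == upper
        assert round(res.loa_lower, 1) == lower

    def test_hand_computed_pairs(self):
        res = bland_altman([(1.0, 0.0), (3.0, 0.0)])
        assert res.mean_diff == pytest.approx(2.0)
        assert res.sd_diff == pytest.approx(np.sqrt(2.0))
        assert res.loa_upper == pytest.approx(2 + 1.96 * np.sqrt(2.0))

    def test_fewer_than_two_pairs_rejected(self):
        with pytest.raises(ValueError):
            bland_altman([(1.0, 0.0)])

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(st.lists(st.tuples(st.floats(-100, 100), st.floats(-100, 100)),
                    min_size=2, max_size=40))
    def test_limits_are_symmetric_about_mean(self, pairs):
        res = bland_altman(pairs)
        assert res.loa_upper == pytest.approx(
            res.mean_diff + 1.96 * res.sd_diff, rel=1e-12, abs=1e-9)
        assert res.loa_upper >= res.loa_lower


class TestBcaBootstrap:
    def test_constant_sample_collapses(self):
        ci = bca_bootstrap_mean_ci([5.0, 5.0, 5.0, 5.0], seed=1)
        assert (ci.estimate, ci.lower, ci.upper) == (5.0, 5.0, 5.0)
        assert ci.degenerate

    def test_seed_reproducibility(self):
        x = np.random.default_rng(2).normal(size=30)
        a = bca_bootstrap_mean_ci(x, seed=42)
        b = bca_bootstrap_mean_ci(x, seed=42)
        assert (a.lower, a.upper) == (b.lower, b.upper)

    def test_matches_scipy_bca_oracle(self):
        x = np.random.default_rng(9).normal(3, 2, 40)
        ours = bca_bootstrap_mean_ci(x, n_boot=4000, seed=11)
        ref = stats.bootstrap((x,), np.mean, n_resamples=4000,
                              confidence_level=0.95, method="BCa",
                              random_state=np.random.default_rng(11))
        assert ours.lower == pytest.approx(ref.confidence_interval.low,
                                           rel=1e-9)
        assert ours.upper == pytest.approx(ref.confidence_interval.high,
                                           rel=1e-9)

    def test_zero_bias_zero_acceleration_is_percentile(self):
        boots = np.random.default_rng(3).normal(size=2001)
        lo, hi = _bca_interval(boots, float(boots.mean()), z0=0.0, accel=0.0,
                               alpha=0.05)
        assert lo == pytest.approx(np.quantile(boots, 0.025))
        assert hi == pytest.approx(np.quantile(boots, 0.975))

    def test_large_symmetric_sample_close_to_t_interval(self):
        x = np.random.default_rng(4).normal(10, 3, 400)
        ci = bca_bootstrap_mean_ci(x, n_boot=4000, seed=5)
        half = stats.t.ppf(0.975, len(x) - 1) * x.std(ddof=1) / np.sqrt(len(x))
        bca_half = (ci.upper - ci.lower) / 2
        assert abs(bca_half - half) / half < 0.05

    def test_too_small_sample_rejected(self):
        with pytest.raises(ValueError):
            bca_bootstrap_mean_ci([1.0])


class TestPillaiManova:
    def test_p1_two_groups_reduces_to_anova_f(self):
        rng = np.random.default_rng(6)
        y = rng.normal(size=50)
        g = np.array(["a"] * 28 + ["b"] * 22)
        y[g == "b"] += 0.6
        res = pillai_manova(y[:, None], groups=g)[0]
        f_ref = stats.f_oneway(y[g == "a"], y[g == "b"])
        assert res.F == pytest.approx(f_ref.statistic, abs=1e-10)
        assert (res.df1, res.df2) == (1, 48)
        assert res.p == pytest.approx(f_ref.pvalue, abs=1e-10)

    def test_one_way_matches_statsmodels(self):
        from statsmodels.multivariate.manova import MANOVA

        rng = np.random.default_rng(5)
        Y = rng.normal(size=(90, 4))
        g = rng.choice(list("abc"), size=90)
        res = pillai_manova(Y, groups=g)[0]
        df = pd.DataFrame(Y, columns=[f"y{i}" for i in range(4)])
        df["g"] = g
        tab = MANOVA.from_formula("y0+y1+y2+y3 ~ C(g)", data=df).mv_test()
        ref = tab.results["C(g)"]["stat"].loc["Pillai's trace"]
        assert res.pillai == pytest.approx(ref["Value"], abs=1e-10)
        assert res.F == pytest.approx(ref["F Value"], abs=1e-8)
        assert (res.df1, res.df2) == (ref["Num DF"], ref["Den DF"])

    def test_unbalanced_two_way_matches_statsmodels_type_iii(self):
        from statsmodels.multivariate.manova import MANOVA

        rng = np.random.default_rng(15)
        n = 100
        Y = rng.normal(size=(n, 3))
        a = rng.choice(list("xyz"), size=n)
        b = rng.choice(list("uv"), size=n)
        ours = {r.effect: r for r in pillai_manova(Y, factors=(a, b))}
        df = pd.DataFrame(Y, columns=["y0", "y1", "y2"])
        df["a"], df["b"] = a, b
        tab = MANOVA.from_formula("y0+y1+y2 ~ C(a, Sum)*C(b, Sum)",
                                  data=df).mv_test()
        for term, key in [("C(a, Sum)", "factor_a"), ("C(b, Sum)", "factor_b"),
                          ("C(a, Sum):C(b, Sum)", "interaction")]:
            ref = tab.results[term]["stat"].loc["Pillai's trace"]
            assert ours[key].pillai == pytest.approx(ref["Value"], abs=1e-10)
            assert ours[key].F == pytest.approx(ref["F Value"], abs=1e-8)

    def test_empty_cell_rejected(self):
        Y = np.random.default_rng(0).normal(size=(30, 2))
        a = np.array(["x"] * 15 + ["y"] * 15)
        b = np.array(["u"] * 15 + ["v"] * 15)  # cells (x,v), (y,u) empty
        with pytest.raises(ValueError, match="empty cell"):
            pillai_manova(Y, factors=(a, b))

    def test_duplicated_response_rejected_with_names(self):
        rng = np.random.default_rng(1)
        y = rng.normal(size=60)
        Y = pd.DataFrame({"u": y, "v": y})
        g = np.array(["a", "b", "c"] * 20)
        with pytest.raises(RankDeficiencyError, match="u~v"):
            pillai_manova(Y, groups=g)


class TestBoxM:
    def test_identical_groups_give_zero(self):
        X = np.random.default_rng(7).normal(size=(40, 3))
        data = np.vstack([X, X])
        g = np.array(["a"] * 40 + ["b"] * 40)
        res = box_m(data, g)
        assert res.M == pytest.approx(0.0, abs=1e-9)
        assert res.p == pytest.approx(1.0)

    def test_detects_inflated_variance(self):
        rng = np.random.default_rng(8)
        a = rng.normal(size=(50, 2))
        b = rng.normal(scale=np.sqrt(10.0), size=(50, 2))
        res = box_m(np.vstack([a, b]), np.array(["a"] * 50 + ["b"] * 50))
        assert res.p < 0.01

    def test_type_i_error_near_alpha(self):
        rng = np.random.default_rng(9)
        hits = 0
        n_sims = 400
        for _ in range(n_sims):
            data = rng.normal(size=(80, 2))
            g = np.array(["a"] * 40 + ["b"] * 40)
            hits += box_m(data, g).p < 0.05
        assert 0.02 <= hits / n_sims <= 0.09

    def test_group_smaller_than_p_rejected(self):
        data = np.random.default_rng(0).normal(size=(6, 4))
        with pytest.raises(ValueError):
            box_m(data, np.array(["a", "a", "a", "b", "b", "b"]))


class TestPearsonScreen:
    def test_duplicated_and_negated_columns_flagged(self):
        rng = np.random.default_rng(10)
        x = rng.normal(size=200)
        df = pd.DataFrame({"x": x, "dup": x, "neg": -x,
                           "noise": rng.normal(size=200)})
        res = pearson_screen(df)
        flagged = {(a, b): r for a, b, r in res.flags}
        assert flagged[("x", "dup")] == pytest.approx(1.0)
        assert flagged[("x", "neg")] == pytest.approx(-1.0)
        assert not any("noise" in pair for pair in flagged)

    def test_independent_columns_not_flagged(self):
        rng = np.random.default_rng(11)
        res = pearson_screen(rng.normal(size=(1000, 5)))
        assert res.flags == []
        off_diag = res.corr.to_numpy()[~np.eye(5, dtype=bool)]
        assert np.abs(off_diag).max() < 0.12

    def test_zero_variance_column_reported_not_crashed(self):
        df = pd.DataFrame({"x": [1.0, 2.0, 3.0], "const": [4.0, 4.0, 4.0]})
        res = pearson_screen(df)
        assert res.undefined == ["const"]


def _brute_force_stable_subsets(X, labels, f_enter=3.84, f_remove=2.71):
    """All variable subsets that are fixed points of the stepwise rules,
    computed by exhaustive enumeration (independent of the stepwise code)."""
    levels = list(pd.unique(labels))
    g = len(levels)
    n, p = X.shape

    def wilks(idx):
        if not idx:
            return 1.0
        Y = X[:, list(idx)]
        grand = Y.mean(axis=0)
        T = (Y - grand).T @ (Y - grand)
        W = np.zeros_like(T)
        for lev in levels:
            sub = Y[labels == lev]
            c = sub - sub.mean(axis=0)
            W += c.T @ c
        return np.linalg.det(W) / np.linalg.det(T)

    def part_f(inc, v):
        lo, ln = wilks(inc), wilks(inc + [v])
        return (n - g - len(inc)) / (g - 1) * (lo / ln - 1)

    stable = []
    for k in range(p + 1):
        for S in combinations(range(p), k):
            S = list(S)
            keeps = all(part_f([u for u in S if u != v], v) > f_remove
                        for v in S)
            stops = all(part_f(S, v) < f_enter
                        for v in range(p) if v not in S)
            if keeps and stops:
                stable.append(tuple(sorted(S)))
    return stable


class TestStepwiseLda:
    def test_widely_separated_groups_classify_perfectly(self):
        x = np.concatenate([np.random.default_rng(0).normal(0, 0.1, 20),
                            np.random.default_rng(1).normal(50, 0.1, 20)])
        g = np.array(["lo"] * 20 + ["hi"] * 20)
        model = stepwise_lda(pd.DataFrame({"x": x}), g)
        table = lda_classification_table(model, pd.DataFrame({"x": x}), g)
        assert table.overall_percent == 100.0
        assert model.wilks_lambda < 0.01

    @pytest.mark.parametrize("seed", range(12))
    def test_selection_matches_brute_force_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n = 30
        X = rng.normal(size=(n, 3))
        labels = rng.choice(list("abc"), size=n)
        X[labels == "a", 0] += 1.5
        X[labels == "c", 1] += 1.0
        stable = _brute_force_stable_subsets(X, labels)
        model = stepwise_lda(pd.DataFrame(X, columns=list("xyz")), labels)
        selected = tuple(sorted("xyz".index(v) for v in model.variables))
        assert selected in stable
        if len(stable) == 1:
            assert selected == stable[0]

    def test_wilks_eigenvalue_identity(self):
        rng = np.random.default_rng(13)
        X = rng.normal(size=(90, 4))
        g = rng.choice(list("pqr"), size=90)
        X[g == "p"] += [0.8, 0, 0, 0.2]
        model = stepwise_lda(pd.DataFrame(X, columns=list("abcd")), g,
                             f_enter=0.1, f_remove=0.05)
        assert model.wilks_lambda * np.prod(1 + model.eigenvalues) == \
            pytest.approx(1.0, abs=1e-10)

    def test_two_group_boundary_matches_univariate_closed_form(self):
        rng = np.random.default_rng(14)
        n1, n2 = 40, 25
        x = np.concatenate([rng.normal(0, 1, n1), rng.normal(2, 1, n2)])
        g = np.array(["a"] * n1 + ["b"] * n2)
        df = pd.DataFrame({"x": x})
        model = stepwise_lda(df, g, priors="proportional")
        # boundary where the two classification-function scores are equal
        c = model.class_coef[:, 0]
        k = model.class_const
        boundary = (k[1] - k[0]) / (c[0] - c[1])
        m1, m2 = x[g == "a"].mean(), x[g == "b"].mean()
        s2 = (((x[g == "a"] - m1) ** 2).sum()
              + ((x[g == "b"] - m2) ** 2).sum()) / (n1 + n2 - 2)
        # closed form: x* = (m1+m2)/2 + s^2 ln(pi2/pi1)/(m1-m2)
        expected = (m1 + m2) / 2 + s2 * np.log(n2 / n1) / (m1 - m2)
        assert boundary == pytest.approx(expected, abs=1e-8)

    def test_two_group_eigenvalue_is_hotelling_t2_over_df(self):
        rng = np.random.default_rng(16)
        n1, n2 = 30, 26
        X = np.vstack([rng.normal(0, 1, (n1, 3)),
                       rng.normal([0.9, 0.2, 0], 1, (n2, 3))])
        g = np.array(["a"] * n1 + ["b"] * n2)
        model = stepwise_lda(pd.DataFrame(X, columns=list("uvw")), g,
                             f_enter=0.1, f_remove=0.05)
        d = X[g == "a"].mean(0) - X[g == "b"].mean(0)
        Sp = (np.cov(X[g == "a"], rowvar=False) * (n1 - 1)
              + np.cov(X[g == "b"], rowvar=False) * (n2 - 1)) / (n1 + n2 - 2)
        t2 = (n1 * n2) / (n1 + n2) * d @ np.linalg.solve(Sp, d)
        # for g=2 with all variables entered the single eigenvalue is
        # T^2/(n-2)
        assert model.eigenvalues[0] == pytest.approx(t2 / (n1 + n2 - 2),
                                                     abs=1e-10)

    def test_equal_prior_predictions_match_sklearn(self):
        from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

        rng = np.random.default_rng(9)
        X = rng.normal(size=(120, 3))
        g = rng.choice(list("pqr"), size=120)
        X[g == "p"] += [1, 0, 0]
        X[g == "r"] += [0, 1.5, 0]
        df = pd.DataFrame(X, columns=list("abc"))
        model = stepwise_lda(df, g, priors="equal")
        sk = LinearDiscriminantAnalysis(priors=[1 / 3] * 3)
        sk.fit(df[model.variables], g)
        assert (model.predict(df) == sk.predict(df[model.variables])).all()

    def test_no_signal_returns_empty_model_with_diagnostic(self):
        rng = np.random.default_rng(17)
        X = rng.normal(size=(60, 2))
        g = rng.choice(["a", "b"], size=60)
        model = stepwise_lda(pd.DataFrame(X, columns=["u", "v"]), g,
                             f_enter=1e6, f_remove=1e5)
        assert model.variables == []
        assert "entry threshold" in model.diagnostic
        with pytest.raises(ValueError):
            model.predict(pd.DataFrame(X, columns=["u", "v"]))

    def test_classification_table_row_sums_equal_group_sizes(self):
        rng = np.random.default_rng(18)
        x = np.concatenate([rng.normal(0, 1, 30), rng.normal(1, 1, 20),
                            rng.normal(2, 1, 10)])
        g = np.array(["a"] * 30 + ["b"] * 20 + ["c"] * 10)
        df = pd.DataFrame({"x": x})
        model = stepwise_lda(df, g, f_enter=0.1, f_remove=0.05)
        table = lda_classification_table(model, df, g)
        assert table.counts.sum(axis=1).tolist() == [30, 20, 10]

    def test_unseen_group_label_rejected(self):
        rng = np.random.default_rng(19)
        x = np.concatenate([rng.normal(0, 1, 20), rng.normal(3, 1, 20)])
        g = np.array(["a"] * 20 + ["b"] * 20)
        df = pd.DataFrame({"x": x})
        model = stepwise_lda(df, g, f_enter=0.1, f_remove=0.05)
        with pytest.raises(ValueError, match="unseen"):
            lda_classification_table(model, df,
                                     np.array(["a"] * 20 + ["z"] * 20))

    def test_structure_coefficients_are_within_group_correlations(self):
        rng = np.random.default_rng(20)
        X = rng.normal(size=(100, 2))
        g = np.array(["a"] * 50 + ["b"] * 50)
        X[g == "b"] += [1.2, 0]
        df = pd.DataFrame(X, columns=["u", "v"])
        model = stepwise_lda(df, g, f_enter=0.1, f_remove=0.05)
        scores = model.transform(df)[:, 0]
        # within-group centered correlation computed independently
        for j, var in enumerate(["u", "v"]):
            xw = np.concatenate([X[g == lev, j] - X[g == lev, j].mean()
                                 for lev in model.groups])
            sw = np.concatenate([scores[g == lev] - scores[g == lev].mean()
                                 for lev in model.groups])
            r = np.corrcoef(xw, sw)[0, 1]
            assert model.structure.loc[var].iloc[0] == pytest.approx(
                r, abs=1e-9)
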