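"""ANCOVA/EMM/MANCOVA against independent GLM oracles, contingency-test
dispatch, BH adjustment, partial correlations, regression, ICC, agreement."""

import math

import numpy as np
import pandas as pd
import pytest
import scipy.stats as sps

from pragmalang.stats import (
    bh_adjust,
    chi_or_fisher,
    emm_pairwise,
    factorial_ancova,
    fisher_exact_rc,
    icc,
    mancova_wilks,
    multiple_regression,
    partial_correlation,
    percent_agreement,
)

# deterministic unbalanced ANCOVA fixture; expected values frozen from
# R (car::Anova type III with sum contrasts; emmeans) on the same data
DX = ["asd"] * 7 + ["non"] * 9
SEX = ["f", "f", "f", "m", "m", "m", "m", "f", "f", "f", "f", "f", "m", "m", "m", "m"]
VIQ = [120.3, 126.4, 121.5, 100.3, 96.1, 110.7, 118.6,
       115.1, 128.1, 117.5, 116.4, 102.7, 98.9, 124.8, 110.5, 118.1]
Y = [3.833, 4.956, 3.954, 3.233, 4.786, 2.84, 4.024,
     4.217, 3.775, 3.873, 3.87, 4.099, 2.536, 4.016, 3.372, 3.968]


def simulated_design(seed=0, n=160):
    rng = np.random.default_rng(seed)
    dx = np.repeat(["asd", "non"], n // 2)
    sex = np.tile(np.repeat(["f", "m"], n // 4), 2)
    viq = rng.normal(110, 12, n)
    y = 0.4 * (dx == "asd") + 0.3 * (sex == "f") + 0.02 * viq + rng.normal(0, 1, n)
    return y, dx, sex, viq


class TestFactorialAncova:
    def test_matches_r_type3_oracle(self):
        with pytest.warns(UserWarning, match="smallest cell"):
            res, _ = factorial_ancova(Y, DX, SEX, VIQ)
        frozen = {  # car::Anova(lm(y ~ dx*sex + viq), type=3)
            "diagnosis": (0.67516, 0.42871),
            "sex": (1.05165, 0.32715),
            "interaction": (0.04491, 0.83605),
            "covariate": (0.46506, 0.50937),
        }
        for r in res:
            f, p = frozen[r.effect]
            assert abs(r.statistic - f) < 5e-5
            assert abs(r.p - p) < 5e-5

    def test_matches_statsmodels_anova_lm_to_1e8(self):
        y, dx, sex, viq = simulated_design(3)
        res, _ = factorial_ancova(y, dx, sex, viq)
        import statsmodels.api as sm
        import statsmodels.formula.api as smf

        df = pd.DataFrame({"y": y, "dx": dx, "sex": sex, "viq": viq})
        model = smf.ols("y ~ C(dx, Sum) * C(sex, Sum) + viq", data=df).fit()
        tab = sm.stats.anova_lm(model, typ=3)
        mapping = {
            "diagnosis": "C(dx, Sum)",
            "sex": "C(sex, Sum)",
            "interaction": "C(dx, Sum):C(sex, Sum)",
            "covariate": "viq",
        }
        for r in res:
            assert abs(r.statistic - tab.loc[mapping[r.effect], "F"]) < 1e-8

    def test_constant_outcome_gives_zero_f(self):
        y = np.ones(40)
        dx = ["a"] * 20 + ["b"] * 20
        sex = (["f"] * 10 + ["m"] * 10) * 2
        viq = np.linspace(90, 120, 40)
        res, _ = factorial_ancova(y, dx, sex, viq)
        for r in res:
            assert r.statistic < 1e-12 and r.p > 0.999999

    def test_orthogonal_covariate_leaves_factor_ss_unchanged(self):
        """With a covariate orthogonal to the (balanced) factor design, the
        factor effect sums of squares equal those of a plain two-way ANOVA
        on the covariate-residualized outcome."""
        rng = np.random.default_rng(7)
        n = 80
        dx = np.repeat(["a", "b"], n // 2)
        sex = np.tile(np.repeat(["f", "m"], n // 4), 2)
        viq = rng.normal(0, 1, n)
        from pragmalang.stats import _ancova_design

        X, *_ = _ancova_design(dx, sex, viq)
        F = X[:, :4]
        viq_orth = viq - F @ np.linalg.lstsq(F, viq, rcond=None)[0]
        y = rng.normal(0, 1, n) + 0.5 * (dx == "a")
        res, fit = factorial_ancova(y, dx, sex, viq_orth)
        # oracle: residualize y on the orthogonal covariate, run two-way ANOVA
        beta = float(viq_orth @ y / (viq_orth @ viq_orth))
        y_res = y - viq_orth * beta
        for name, col in {"diagnosis": 1, "sex": 2, "interaction": 3}.items():
            rss_f = float(np.sum((y_res - F @ np.linalg.lstsq(F, y_res, rcond=None)[0]) ** 2))
            F_red = np.delete(F, col, axis=1)
            rss_r = float(np.sum((y_res - F_red @ np.linalg.lstsq(F_red, y_res, rcond=None)[0]) ** 2))
            ss_oracle = rss_r - rss_f
            r = next(x for x in res if x.effect == name)
            ss_ours = r.statistic * fit.sigma2
            assert abs(ss_ours - ss_oracle) < 1e-8

    def test_partial_eta_squared_in_unit_interval(self):
        y, dx, sex, viq = simulated_design(11)
        res, _ = factorial_ancova(y, dx, sex, viq)
        for r in res:
            assert 0.0 <= r.effect_size <= 1.0 and r.statistic >= 0


class TestEMM:
    def test_matches_r_emmeans_oracle(self):
        with pytest.warns(UserWarning):
            _, fit = factorial_ancova(Y, DX, SEX, VIQ)
        emm, con = emm_pairwise(fit, "diagnosis")
        assert np.allclose(emm["emmean"], [3.978115, 3.714634], atol=1e-6)
        assert np.allclose(emm["se"], [0.24109054, 0.21174762], atol=1e-6)
        assert abs(con["estimate"].item() - 0.26348097) < 1e-6
        assert abs(con["t"].item() - 0.822) < 1e-3
        emm2, con2 = emm_pairwise(fit, "sex")
        assert np.allclose(emm2["emmean"], [4.037176, 3.655573], atol=1e-6)
        assert abs(con2["p"].item() - 0.3272) < 1e-4

    def test_balanced_orthogonal_covariate_emms_equal_cell_means(self):
        rng = np.random.default_rng(2)
        n = 40
        dx = np.repeat(["a", "b"], n // 2)
        sex = np.tile(np.repeat(["f", "m"], n // 4), 2)
        from pragmalang.stats import _ancova_design

        viq = rng.normal(0, 1, n)
        F, *_ = _ancova_design(dx, sex, viq)
        viq = viq - F[:, :4] @ np.linalg.lstsq(F[:, :4], viq, rcond=None)[0]
        y = rng.normal(0, 1, n)
        _, fit = factorial_ancova(y, dx, sex, viq)
        emm, _ = emm_pairwise(fit, "diagnosis")
        assert abs(emm["emmean"][0] - y[dx == "a"].mean()) < 1e-10

    def test_identical_groups_give_t_zero(self):
        n = 40
        dx = np.repeat(["a", "b"], n // 2)
        sex = np.tile(np.repeat(["f", "m"], n // 4), 2)
        y = np.tile(np.arange(n // 2), 2).astype(float)
        y = np.concatenate([y[: n // 2], y[: n // 2]])  # same in both dx groups
        viq = np.tile(np.linspace(-1, 1, n // 2), 2)
        _, fit = factorial_ancova(y, dx, sex, viq)
        _, con = emm_pairwise(fit, "diagnosis")
        assert abs(con["estimate"].item()) < 1e-10


class TestMancova:
    def test_univariate_reduces_to_ancova_f(self):
        y, dx, sex, viq = simulated_design(5)
        uni, _ = factorial_ancova(y, dx, sex, viq)
        multi = mancova_wilks(y[:, None], dx, sex, viq)
        for a, b in zip(uni, multi):
            assert abs(a.statistic - b.statistic) < 1e-8
            assert abs(a.p - b.p) < 1e-10

    def test_lambda_in_unit_interval_and_statsmodels_match(self):
        rng = np.random.default_rng(123)
        y1, dx, sex, viq = simulated_design(9)
        Y = np.column_stack([y1, y1 * 0.5 + rng.normal(0, 1, len(y1))])
        res = mancova_wilks(Y, dx, sex, viq)
        for r in res:
            assert 0.0 < r.extra["wilks_lambda"] <= 1.0
        from statsmodels.multivariate.manova import MANOVA

        df = pd.DataFrame({"y1": Y[:, 0], "y2": Y[:, 1], "dx": dx, "sex": sex, "viq": viq})
        mv = MANOVA.from_formula(
            "y1 + y2 ~ C(dx, Sum) * C(sex, Sum) + viq", data=df
        ).mv_test()
        sm_lambda = mv.results["C(dx, Sum)"]["stat"].loc["Wilks' lambda", "Value"]
        ours = next(r for r in res if r.effect == "diagnosis")
        assert abs(ours.extra["wilks_lambda"] - float(sm_lambda)) < 1e-8


class TestContingency:
    def test_fisher_branch_and_hypergeometric_value(self):
        res = chi_or_fisher([[3, 1], [1, 3]])
        assert res.test == "fisher"
        # point-probability two-sided p for this symmetric table = 2 * 17/70
        assert abs(res.p - 2 * 17 / 70) < 1e-12

    def test_one_sided_tail_mass_17_70(self):
        # P(X >= 3), X ~ Hypergeom(N=8, K=4, n=4)
        tail = sps.hypergeom.pmf([3, 4], 8, 4, 4).sum()
        assert abs(tail - 17 / 70) < 1e-12

    def test_balanced_table_chi_square_zero(self):
        res = chi_or_fisher([[50, 50], [50, 50]])
        assert res.test == "chi2"
        assert res.statistic == 0.0 and res.p == 1.0

    def test_20_percent_rule_on_2x3_table(self):
        res = chi_or_fisher([[20, 20, 1], [20, 20, 2]])
        assert res.test == "fisher"
        res2 = chi_or_fisher([[20, 20, 20], [20, 20, 20]])
        assert res2.test == "chi2"

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError, match="margin"):
            chi_or_fisher([[0, 0], [1, 2]])

    def test_rc_fisher_matches_r_oracle_values(self):
        # frozen from R fisher.test: 2x3 and 3x3 tables
        assert abs(fisher_exact_rc(np.array([[1, 2, 5], [4, 3, 0]])) - 0.0675990676) < 1e-9
        assert abs(
            fisher_exact_rc(np.array([[3, 0, 1], [0, 4, 2], [2, 1, 3]])) - 0.09614195328
        ) < 1e-9

    def test_2x2_fisher_matches_scipy(self, rng):
        for _ in range(50):
            tbl = rng.integers(0, 8, size=(2, 2))
            if (tbl.sum(axis=0) == 0).any() or (tbl.sum(axis=1) == 0).any():
                continue
            assert abs(fisher_exact_rc(tbl) - sps.fisher_exact(tbl)[1]) < 1e-10


class TestBH:
    def test_stepup_worked_example(self):
        adj, _ = bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(adj, [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        adj, rej = bh_adjust([0.03], q=0.10)
        assert adj[0] == 0.03 and rej[0]

    def test_matches_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests

        for _ in range(20):
            p = rng.random(rng.integers(1, 30))
            adj, rej = bh_adjust(p, q=0.10)
            sm_rej, sm_adj, *_ = multipletests(p, alpha=0.10, method="fdr_bh")
            assert np.allclose(adj, sm_adj)
            assert np.array_equal(rej, sm_rej)

    def test_adjusted_monotone_in_sorted_order_and_geq_raw(self, rng):
        p = rng.random(25)
        adj, _ = bh_adjust(p)
        assert np.all(adj >= p - 1e-15)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-15)

    def test_never_more_rejections_than_unadjusted(self, rng):
        for _ in range(20):
            p = rng.random(15)
            adj, rej = bh_adjust(p, q=0.05)
            assert rej.sum() <= np.sum(p <= 0.05)


class TestPartialCorrelation:
    def test_uncorrelated_covariate_equals_plain_pearson(self, rng):
        x, y = rng.normal(size=(2, 200))
        z = rng.normal(size=200)
        D = np.column_stack([np.ones(200), x, y])
        z = z - D @ np.linalg.lstsq(D, z, rcond=None)[0]  # sample-orthogonal
        r, _ = partial_correlation(x, y, z)
        assert abs(r - np.corrcoef(x, y)[0, 1]) < 1e-10

    def test_x_equals_z_gives_zero(self, rng):
        z = rng.normal(size=100)
        y = rng.normal(size=100)
        r, p = partial_correlation(z, y, z)
        assert math.isnan(r)  # residual of x on z is constant

    def test_matches_pingouin(self, rng):
        pingouin = pytest.importorskip("pingouin")
        x, y, z = rng.normal(size=(3, 80))
        y = y + 0.5 * x + 0.3 * z
        r, p = partial_correlation(x, y, z)
        out = pingouin.partial_corr(
            pd.DataFrame({"x": x, "y": y, "z": z}), x="x", y="y", covar="z"
        )
        assert abs(r - out["r"].item()) < 1e-10
        assert abs(p - out["p_val"].item()) < 1e-10


class TestRegression:
    def test_exact_linear_relationship_r2_one(self):
        x = np.arange(20.0)
        out = multiple_regression(2.0 + 3.0 * x, pd.DataFrame({"x": x}))
        assert abs(out["r_squared"] - 1.0) < 1e-12

    def test_coefficients_match_normal_equations(self, rng):
        n = 100
        X = pd.DataFrame(rng.normal(size=(n, 3)), columns=["a", "b", "c"])
        y = 1.0 + X["a"] * 0.5 - X["b"] * 0.2 + rng.normal(0, 1, n)
        out = multiple_regression(y, X)
        D = np.column_stack([np.ones(n), X.to_numpy()])
        beta = np.linalg.solve(D.T @ D, D.T @ y)
        assert np.allclose(out["coefficients"]["coef"].to_numpy(), beta, atol=1e-10)

    def test_collinear_design_rejected(self):
        x = np.arange(30.0)
        with pytest.raises(ValueError, match="condition"):
            multiple_regression(x, pd.DataFrame({"a": x, "b": 2 * x}))

    def test_gate_flag_reflects_omnibus(self, rng):
        n = 60
        X = pd.DataFrame({"noise": rng.normal(size=n)})
        out = multiple_regression(rng.normal(size=n), X)
        assert out["gate_passed"] == (out["f_p"] < 0.05)


class TestReliability:
    def test_identical_raters_icc_one(self, rng):
        x = rng.normal(size=10)
        value, label = icc(np.column_stack([x, x]))
        assert abs(value - 1.0) < 1e-9 and label == "excellent"

    def test_matches_pingouin_icc2(self, rng):
        pingouin = pytest.importorskip("pingouin")
        ratings = rng.normal(size=(12, 2)) + rng.normal(size=(12, 1))
        value, _ = icc(ratings)
        df = pd.DataFrame(
            {
                "item": np.repeat(np.arange(12), 2),
                "rater": np.tile(["a", "b"], 12),
                "score": ratings.ravel(),
            }
        )
        out = pingouin.intraclass_corr(df, targets="item", raters="rater", ratings="score")
        expected = out.loc[out["Type"] == "ICC(A,1)", "ICC"].item()
        assert abs(value - expected) < 1e-8

    def test_agreement_bands(self):
        rng = np.random.default_rng(4)
        base = rng.normal(size=(30, 1))
        good = icc(np.hstack([base, base + rng.normal(0, 0.3, (30, 1))]))[0]
        assert 0.5 < good <= 1.0

    def test_zero_item_variance_undefined(self):
        value, label = icc(np.zeros((5, 2)))
        assert math.isnan(value) and label == "undefined"

    def test_percent_agreement(self):
        assert percent_agreement(["a", "b"], ["a", "b"]) == 100.0
        assert percent_agreement(["a", "b"], ["b", "a"]) == 0.0
        assert percent_agreement(list("aabb"), list("aaba")) == 75.0
        with pytest.raises(ValueError):
            percent_agreement([], [])
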