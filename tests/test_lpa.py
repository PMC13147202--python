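"""Latent profile analysis: z-scoring, EM fitting, information criteria,
entropy, BLRT, model selection, and membership contingency tests."""

import math

import numpy as np
import pandas as pd
import pytest

from pragmalang.lpa import (
    LPAModel,
    blrt,
    classification_entropy,
    fit_lpa,
    information_criteria,
    profile_membership_test,
    select_model,
    zscore_matrix,
)
from pragmalang.simulate import generate_profile_data

SEP_MEANS = np.vstack([np.zeros(4), np.full(4, 3.0)])


@pytest.fixture(scope="module")
def separated():
    X, labels = generate_profile_data(
        2, [0.5, 0.5], SEP_MEANS, np.ones((2, 4)), n=200, seed=42
    )
    return X, labels


class TestZScore:
    def test_columns_standardized_and_invertible(self, rng):
        raw = pd.DataFrame(
            {"id": [f"p{i}" for i in range(50)],
             "a": rng.normal(3, 2, 50), "b": rng.normal(-1, 0.5, 50)}
        )
        fm = zscore_matrix(raw)
        assert np.allclose(fm.X.mean(axis=0), 0, atol=1e-12)
        assert np.allclose(fm.X.std(axis=0, ddof=1), 1, atol=1e-12)
        assert np.allclose(fm.inverse_transform(), raw[["a", "b"]].to_numpy())

    def test_already_standard_column_unchanged(self, rng):
        x = rng.normal(size=80)
        x = (x - x.mean()) / x.std(ddof=1)
        fm = zscore_matrix(pd.DataFrame({"x": x}))
        assert np.allclose(fm.X[:, 0], x, atol=1e-12)

    def test_constant_column_error_names_it(self):
        raw = pd.DataFrame({"ok": [1.0, 2.0, 3.0], "flat": [5.0, 5.0, 5.0]})
        with pytest.raises(ValueError, match="flat"):
            zscore_matrix(raw)

    def test_listwise_deletion(self, rng):
        raw = pd.DataFrame({"a": [1.0, np.nan, 3.0, 4.0], "b": [1.0, 2.0, 3.0, 5.0]})
        fm = zscore_matrix(raw)
        assert fm.n == 3


class TestFitLPA:
    def test_k1_matches_sample_moments(self, rng):
        X = rng.normal(2.0, 1.5, size=(120, 3))
        m = fit_lpa(X, k=1)
        assert np.allclose(m.means[0], X.mean(axis=0))
        assert np.allclose(m.variances[0], X.var(axis=0))
        assert math.isnan(m.entropy)

    def test_planted_two_cluster_recovery(self, separated):
        X, labels = separated
        m = fit_lpa(X, k=2, restarts=10, seed=0)
        order = np.argsort(m.means[:, 0])
        err = np.abs(m.means[order] - SEP_MEANS).mean()
        assert err < 0.1
        agree = max(
            np.mean(m.assignments == labels), np.mean(1 - m.assignments == labels)
        )
        assert agree >= 0.95
        assert m.entropy > 0.9

    def test_loglik_monotone_nondecreasing(self, separated):
        X, _ = separated
        for seed in range(5):
            m = fit_lpa(X, k=3, restarts=1, seed=seed)
            assert np.all(np.diff(m.loglik_path) >= -1e-7)

    def test_deterministic_given_seed(self, separated):
        X, _ = separated
        a = fit_lpa(X, k=2, restarts=3, seed=5)
        b = fit_lpa(X, k=2, restarts=3, seed=5)
        assert a.loglik == b.loglik and np.array_equal(a.assignments, b.assignments)

    def test_row_shuffling_invariance(self, separated):
        X, _ = separated
        perm = np.random.default_rng(1).permutation(len(X))
        a = fit_lpa(X, k=2, restarts=5, seed=3)
        b = fit_lpa(X[perm], k=2, restarts=5, seed=3)
        assert abs(a.loglik - b.loglik) < 1e-6

    def test_posterior_rows_sum_to_one(self, separated):
        X, _ = separated
        m = fit_lpa(X, k=3, restarts=5, seed=2)
        assert np.allclose(m.posteriors.sum(axis=1), 1.0)
        assert np.isclose(m.weights.sum(), 1.0)

    def test_invalid_k_and_small_n(self):
        X = np.random.default_rng(0).normal(size=(5, 2))
        with pytest.raises(ValueError):
            fit_lpa(X, k=0)
        with pytest.raises(ValueError):
            fit_lpa(X, k=5)


class TestInformationCriteria:
    def test_formula_on_fixed_loglik(self):
        m = LPAModel(
            k=1, weights=np.ones(1), means=np.zeros((1, 1)),
            variances=np.ones((1, 1)), loglik=-150.0,
            posteriors=np.ones((100, 1)), aic=0, bic=0, entropy=float("nan"),
            assignments=np.zeros(100, dtype=int), seed=0, restarts=1, n_iter=1,
        )
        aic, bic = information_criteria(m)
        assert aic == 304.0  # p = 2 for k=1, d=1
        assert np.isclose(bic, 300.0 + 2.0 * math.log(100))

    def test_parameter_count_matches_bruteforce(self, separated):
        X, _ = separated
        for k in (1, 2, 3):
            m = fit_lpa(X, k=k, restarts=3, seed=1)
            d = X.shape[1]
            brute = (k - 1) + k * d + k * d  # weights + means + variances
            assert m.n_parameters == brute

    def test_bic_exceeds_aic_for_large_n(self, separated):
        X, _ = separated
        m = fit_lpa(X, k=2, restarts=3, seed=1)
        assert m.bic > m.aic  # ln(200) > 2


class TestEntropy:
    def test_crisp_posteriors_give_one(self):
        post = np.eye(3)[np.array([0, 1, 2, 0])]
        m = LPAModel(
            k=3, weights=np.full(3, 1 / 3), means=np.zeros((3, 1)),
            variances=np.ones((3, 1)), loglik=0.0, posteriors=post,
            aic=0, bic=0, entropy=0, assignments=post.argmax(axis=1),
            seed=0, restarts=1, n_iter=1,
        )
        assert classification_entropy(m) == 1.0

    def test_uniform_posteriors_give_zero(self):
        post = np.full((6, 2), 0.5)
        m = LPAModel(
            k=2, weights=np.full(2, 0.5), means=np.zeros((2, 1)),
            variances=np.ones((2, 1)), loglik=0.0, posteriors=post,
            aic=0, bic=0, entropy=0, assignments=post.argmax(axis=1),
            seed=0, restarts=1, n_iter=1,
        )
        assert abs(classification_entropy(m)) < 1e-12

    def test_hand_computed_fixture(self):
        post = np.array([[0.9, 0.1], [0.2, 0.8], [0.5, 0.5]])
        m = LPAModel(
            k=2, weights=np.full(2, 0.5), means=np.zeros((2, 1)),
            variances=np.ones((2, 1)), loglik=0.0, posteriors=post,
            aic=0, bic=0, entropy=0, assignments=post.argmax(axis=1),
            seed=0, restarts=1, n_iter=1,
        )
        ent = -(post * np.log(post)).sum()
        assert np.isclose(classification_entropy(m), 1 - ent / (3 * math.log(2)))


class TestBLRT:
    def test_add_one_formula_on_fixture(self, separated):
        X, _ = separated
        res = blrt(X, 2, n_boot=19, seed=4, restarts=2)
        exceed = int(np.sum(res.boot_lrts >= res.observed_lrt))
        assert res.p_value == (1 + exceed) / (1 + 19)

    def test_separated_truth_rejects(self, separated):
        X, _ = separated
        res = blrt(X, 2, n_boot=49, seed=8, restarts=2)
        assert res.p_value < 0.05

    def test_k_below_two_rejected(self, separated):
        with pytest.raises(ValueError):
            blrt(separated[0], 1)


class TestSelectModel:
    def test_single_cluster_truth_selects_k1(self, rng):
        X = rng.normal(size=(150, 3))
        table = select_model(X, k_range=range(1, 4), restarts=5, seed=9)
        assert table.loc[table["bic_minimal"], "k"].item() == 1

    def test_one_row_per_k_with_table5_style_columns(self, separated):
        X, _ = separated
        table = select_model(X, k_range=range(1, 4), restarts=5, seed=2)
        assert list(table["k"]) == [1, 2, 3]
        for col in ("aic", "bic", "entropy", "smallest_proportion",
                    "largest_proportion"):
            assert col in table.columns
        assert math.isnan(table.loc[0, "entropy"])  # k=1 reported as missing

    def test_small_profile_flagged(self, separated):
        X, _ = separated
        table = select_model(X, k_range=[2], restarts=5, seed=2, min_proportion=0.6)
        assert table["small_profile_flag"].item()


class TestMembership:
    def test_balanced_table_not_flagged(self):
        assignments = [0] * 20 + [1] * 20
        labels = (["a"] * 10 + ["b"] * 10) * 2
        out = profile_membership_test(assignments, labels)
        assert not out["flagged"].any()
        assert (out["p"] > 0.99).all()

    def test_concentrated_group_flagged(self):
        assignments = [0] * 20 + [1] * 20
        labels = ["a"] * 18 + ["b"] * 2 + ["b"] * 18 + ["a"] * 2
        out = profile_membership_test(assignments, labels)
        flagged = out[out["flagged"]]
        assert {("a", 0), ("b", 1)} <= {
            (r.group, r.profile) for r in flagged.itertuples()
        }

    def test_margins_conserved(self):
        rng = np.random.default_rng(3)
        assignments = rng.integers(0, 3, 60)
        labels = rng.choice(["a", "b"], 60)
        out = profile_membership_test(assignments, labels)
        for prof in range(3):
            sub = out[out["profile"] == prof]
            assert sub["observed"].sum() == int(np.sum(assignments == prof))


def test_sklearn_gaussian_mixture_agrees_on_loglik(separated):
    """Independent cross-check: our EM reaches the same solution quality as
    sklearn's diagonal Gaussian mixture on well-separated data."""
    sklearn = pytest.importorskip("sklearn.mixture")
    X, _ = separated
    ours = fit_lpa(X, k=2, restarts=10, seed=0)
    gm = sklearn.GaussianMixture(
        n_components=2, covariance_type="diag", n_init=10, random_state=0,
        reg_covar=1e-6, tol=1e-6,
    ).fit(X)
    assert abs(ours.loglik - gm.score(X) * len(X)) < 0.5
    order_ours = np.argsort(ours.means[:, 0])
    order_sk = np.argsort(gm.means_[:, 0])
    assert np.allclose(ours.means[order_ours], gm.means_[order_sk], atol=0.05)
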