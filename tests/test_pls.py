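"""Behavioral PLS: preprocessing, SVD geometry, inference machinery."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import brainstates as bs
from brainstates.pls import (
    age_polynomials,
    bootstrap_bsr,
    build_feature_models,
    fdr_adjust,
    impute_by_age_decile,
    permutation_test,
    pls_svd,
    prepare_cognitive_block,
    quantile_normalize,
    regress_covariates,
)
from brainstates.synthetic import COGNITIVE_SCORES


def small_cohort(n=60, seed=0, missing=()):
    rng = np.random.default_rng(seed)
    df = pd.DataFrame({"age": np.linspace(20, 85, n)})
    for name in COGNITIVE_SCORES:
        df[name] = rng.normal(size=n)
    for (row, col) in missing:
        df.loc[row, col] = np.nan
    return df


class TestImputation:
    def test_no_missing_is_identity(self):
        df = small_cohort()
        out = impute_by_age_decile(df)
        pd.testing.assert_frame_equal(out, df)

    def test_decile_median_value(self):
        df = small_cohort(n=50)
        # subjects 0-4 are the youngest decile; make the median unambiguous
        df.loc[0:4, "naming"] = [1.0, 2.0, 3.0, np.nan, np.nan]
        out = impute_by_age_decile(df)
        assert out.loc[3, "naming"] == 2.0
        assert out.loc[4, "naming"] == 2.0

    def test_subject_with_too_many_missing_excluded(self):
        df = small_cohort(missing=[(7, c) for c in COGNITIVE_SCORES[:4]])
        out = impute_by_age_decile(df)
        assert len(out) == len(df) - 1
        assert not out[COGNITIVE_SCORES].isna().any().any()


class TestCovariateRegression:
    def test_intercept_only_centers(self, rng):
        Y = rng.normal(size=(40, 3)) + 5.0
        res = regress_covariates(Y, np.empty((40, 0)))
        assert np.allclose(res, Y - Y.mean(axis=0), atol=1e-10)

    def test_exactly_linear_response_zero_residual(self, rng):
        C = rng.normal(size=(30, 2))
        Y = C @ rng.normal(size=(2, 4)) + 3.0
        res = regress_covariates(Y, C)
        assert np.max(np.abs(res)) < 1e-10

    def test_manual_normal_equations(self):
        # 4 subjects, 1 covariate, worked by hand via (C'C)^-1 C'y
        c = np.array([1.0, 2.0, 3.0, 4.0])
        y = np.array([2.0, 3.0, 5.0, 6.0])[:, None]
        # with intercept: beta1 = cov(c,y)/var(c) = 1.4, beta0 = 4 - 1.4*2.5 = 0.5
        expected = y.ravel() - (0.5 + 1.4 * c)
        res = regress_covariates(y, c[:, None])
        assert np.allclose(res.ravel(), expected, atol=1e-12)

    def test_residuals_orthogonal_to_covariates(self, rng):
        C = rng.normal(size=(50, 3))
        Y = rng.normal(size=(50, 2))
        res = regress_covariates(Y, C)
        full = np.column_stack([np.ones(50), C])
        assert np.max(np.abs(full.T @ res)) < 1e-8

    def test_collinear_covariates_rejected(self, rng):
        C = rng.normal(size=(20, 2))
        C = np.column_stack([C, C[:, 0] * 2.0])
        with pytest.raises(ValueError, match="collinear"):
            regress_covariates(rng.normal(size=(20, 2)), C)


class TestQuantileNormalize:
    def test_blom_formula_n3(self):
        out = quantile_normalize(np.array([10.0, -2.0, 5.0]))
        expected_sorted = stats.norm.ppf((np.array([1, 2, 3]) - 0.375) / 3.25)
        assert np.allclose(np.sort(out), expected_sorted, atol=1e-12)
        # rank order preserved: -2 < 5 < 10
        assert out[1] < out[2] < out[0]

    def test_rank_preservation(self, rng):
        x = rng.normal(size=100) ** 3  # skewed
        z = quantile_normalize(x)
        assert stats.spearmanr(x, z).statistic == pytest.approx(1.0)

    def test_symmetric_about_zero(self):
        z = quantile_normalize(np.array([1.0, 2.0, 3.0, 4.0, 5.0]))
        assert np.allclose(z + z[::-1], 0.0, atol=1e-12)

    def test_all_tied_rejected(self):
        with pytest.raises(ValueError):
            quantile_normalize(np.ones(10))


class TestAgePolynomials:
    def test_knot_maps_to_zero(self):
        ages = np.array([30.0, 55.0, 80.0])
        cols = age_polynomials(ages, knot=55.0)
        assert cols[1, 0] == 0.0 and cols[1, 1] == 0.0

    def test_raw_values_scale_together(self):
        # -(45-55)^2 = -100 ascending, 0 descending; -(65-55)^2 on the other side
        ages = np.array([35.0, 45.0, 55.0, 65.0, 75.0])
        cols = age_polynomials(ages, knot=55.0)
        # per-column rescaling preserves within-column ratios
        assert cols[1, 0] / cols[0, 0] == pytest.approx(100.0 / 400.0)
        assert cols[3, 1] / cols[4, 1] == pytest.approx(100.0 / 400.0)
        assert cols[1, 1] == 0.0 and cols[3, 0] == 0.0

    def test_monotonicity(self):
        ages = np.linspace(20, 88, 50)
        cols = age_polynomials(ages)
        assert np.all(np.diff(cols[:, 0]) >= 0)  # ascending column non-decreasing
        assert np.all(np.diff(cols[:, 1]) <= 0)  # descending column non-increasing

    def test_rescaled_to_age_scale(self):
        ages = np.linspace(20, 88, 200)
        cols = age_polynomials(ages)
        assert np.allclose(cols.std(axis=0), ages.std(), rtol=1e-12)

    def test_degenerate_age_variance_rejected(self):
        with pytest.raises(ValueError):
            age_polynomials(np.full(10, 55.0))


class TestPlsSvd:
    def test_rank_one_identity(self, rng):
        x = rng.normal(size=(50, 1))
        res = pls_svd(x, 2.0 * x)
        assert res.singular_values.shape == (1,)
        assert res.singular_values[0] == pytest.approx(50 / 49)
        assert abs(res.brain_saliences[0, 0]) == 1.0
        assert abs(res.cognitive_saliences[0, 0]) == 1.0

    def test_null_singular_values_smaller_than_planted(self, rng):
        n = 1000
        X0, Y0 = rng.normal(size=(n, 5)), rng.normal(size=(n, 5))
        null_s = pls_svd(X0, Y0).singular_values[0]
        z = rng.normal(size=n)
        Xp = X0 + z[:, None]
        Yp = Y0 + z[:, None]
        planted_s = pls_svd(Xp, Yp).singular_values[0]
        assert planted_s > 3 * null_s

    def test_orthonormal_saliences_and_explained_fractions(self, rng):
        res = pls_svd(rng.normal(size=(80, 6)), rng.normal(size=(80, 4)))
        U, V = res.brain_saliences, res.cognitive_saliences
        assert np.allclose(U.T @ U, np.eye(4), atol=1e-8)
        assert np.allclose(V.T @ V, np.eye(4), atol=1e-8)
        assert res.explained_fraction.sum() == pytest.approx(1.0, abs=1e-12)

    def test_sign_convention_largest_cognitive_salience_positive(self, rng):
        res = pls_svd(rng.normal(size=(60, 5)), rng.normal(size=(60, 3)))
        for i in range(res.singular_values.size):
            j = np.argmax(np.abs(res.cognitive_saliences[:, i]))
            assert res.cognitive_saliences[j, i] > 0

    def test_zero_variance_column_rejected(self, rng):
        X = rng.normal(size=(30, 3))
        X[:, 1] = 7.0
        with pytest.raises(ValueError, match="1"):
            pls_svd(X, rng.normal(size=(30, 2)))

    def test_subject_shuffle_equivariance(self, rng):
        X = rng.normal(size=(40, 4))
        Y = rng.normal(size=(40, 3))
        perm = rng.permutation(40)
        a = pls_svd(X, Y)
        b = pls_svd(X[perm], Y[perm])
        assert np.allclose(a.singular_values, b.singular_values, atol=1e-10)
        assert np.allclose(a.brain_saliences, b.brain_saliences, atol=1e-10)


class TestPermutation:
    def test_overwhelming_effect_reaches_minimum_p(self, rng):
        n = 200
        z = rng.normal(size=n)
        X = z[:, None] + 0.01 * rng.normal(size=(n, 3))
        Y = z[:, None] + 0.01 * rng.normal(size=(n, 3))
        p = permutation_test(X, Y, n_perm=500, seed=0)
        assert p[0] == pytest.approx(1.0 / 501.0)

    def test_p_never_zero(self, rng):
        p = permutation_test(rng.normal(size=(50, 3)), rng.normal(size=(50, 3)),
                             n_perm=100, seed=1)
        assert np.all(p > 0.0) and np.all(p <= 1.0)

    def test_too_few_permutations_rejected(self, rng):
        with pytest.raises(ValueError):
            permutation_test(rng.normal(size=(50, 3)), rng.normal(size=(50, 3)), n_perm=10)


class TestBootstrap:
    def test_planted_feature_salient_null_feature_not(self, rng):
        n = 300
        z = rng.normal(size=n)
        X = np.column_stack([z + 0.3 * rng.normal(size=n), rng.normal(size=(n, 3))])
        Y = np.column_stack([z + 0.3 * rng.normal(size=n), rng.normal(size=(n, 2))])
        res = bootstrap_bsr(X, Y, n_boot=200, seed=0)
        assert abs(res.bsr_brain[0, 0]) >= 3.0
        assert np.all(np.abs(res.bsr_brain[1:, 0]) < 3.0)

    def test_scale_invariance(self, rng):
        X = rng.normal(size=(100, 4))
        Y = rng.normal(size=(100, 3))
        a = bootstrap_bsr(X, Y, n_boot=100, seed=2)
        b = bootstrap_bsr(2.0 * X, Y, n_boot=100, seed=2)
        assert np.allclose(a.bsr_brain, b.bsr_brain, atol=1e-10)
        assert np.allclose(a.bsr_cognitive, b.bsr_cognitive, atol=1e-10)


class TestFdr:
    def test_single_p_unchanged(self):
        assert fdr_adjust(np.array([0.03]))[0] == pytest.approx(0.03)

    def test_hand_bh_computation(self):
        adj = fdr_adjust(np.array([0.01, 0.02, 0.03]))
        assert np.allclose(adj, [0.03, 0.03, 0.03])

    def test_all_ones_stay_one(self):
        assert np.all(fdr_adjust(np.ones(5)) == 1.0)

    def test_adjusted_at_least_raw_and_rank_monotone(self, rng):
        p = rng.uniform(size=20)
        adj = fdr_adjust(p)
        assert np.all(adj >= p - 1e-15)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-15)


class TestFeatureModels:
    def _metrics(self, K, n_subj, rng):
        out = []
        for s in range(n_subj):
            path = rng.integers(0, K, size=300)
            out.append(bs.state_metrics(path, K, fs=250.0, subject_id=f"s{s}"))
        return out

    def test_column_counts_k8(self, rng):
        models = build_feature_models(self._metrics(8, 5, rng))
        assert models["temporal"][0].shape == (5, 32)
        assert models["transition"][0].shape == (5, 56)

    def test_column_counts_k2(self, rng):
        models = build_feature_models(self._metrics(2, 4, rng))
        assert models["transition"][0].shape == (4, 2)

    def test_never_visited_state_mean_imputed(self, rng):
        ms = self._metrics(3, 6, rng)
        # subject 0 never visits state 2
        import warnings as w

        path = np.array([0, 1] * 150)
        with w.catch_warnings():
            w.simplefilter("ignore")
            ms[0] = bs.state_metrics(path, 3, fs=250.0)
        with pytest.warns(UserWarning, match="imputing"):
            models = build_feature_models(ms)
        M = models["temporal"][0]
        assert np.all(np.isfinite(M))


def test_prepare_cognitive_block_shapes_and_names():
    cohort, _, _ = bs.simulate_cohort(
        np.zeros((120, 4)), bs.CohortConfig(n_subjects=120, seed=3)
    )
    Y, names = prepare_cognitive_block(cohort)
    assert Y.shape == (120, 11)  # 8 scores + education + 2 age polynomials
    assert names[-2:] == ["age_ascending", "age_descending"]
    # residualized, normalized scores are near standard normal
    assert np.all(np.abs(Y[:, :8].mean(axis=0)) < 0.05)
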