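import itertools

import numpy as np
import pytest

from omnik import SampleMetadata
from omnik.kernel_association_test import (
    PermutationPlan,
    build_endogenous,
    empirical_pvalue,
    fit_null,
    leave_one_out_pvalues,
    minp_single_kernel,
    score_stat,
    single_kernel_test,
)
from omnik.surrogate_pca import SurrogateVariants, extract_surrogates

from naive_reference import naive_full_analysis


class TestFitNull:
    def test_exact_fit_recovers_coefficients(self):
        T = np.array([0.0, 1.0, 0.0, 1.0, 1.0])
        meta = SampleMetadata(2 + 3 * T, T, None, "gaussian")
        fit = fit_null(meta)
        np.testing.assert_allclose(fit.residuals, 0, atol=1e-10)
        assert fit.coefficients[1] == pytest.approx(3.0)

    def test_residuals_orthogonal_to_design(self, gaussian_meta):
        fit = fit_null(gaussian_meta)
        np.testing.assert_allclose(fit.design.T @ fit.residuals, 0, atol=1e-8)

    def test_binomial_fitted_in_unit_interval(self, rng):
        n = 60
        T = rng.binomial(1, 0.5, n).astype(float)
        Z = rng.normal(size=(n, 1))
        y = rng.binomial(1, 1 / (1 + np.exp(-(0.3 * T + 0.5 * Z[:, 0])))).astype(float)
        fit = fit_null(SampleMetadata(y, T, Z, "binomial"))
        assert np.all((fit.fitted > 0) & (fit.fitted < 1))
        # score equations hold at the MLE
        np.testing.assert_allclose(fit.design.T @ fit.residuals, 0, atol=1e-6)

    def test_degenerate_binomial_response(self):
        with pytest.raises(ValueError, match="degenerate"):
            fit_null(SampleMetadata(np.ones(6), np.arange(6.0), None, "binomial"))

    def test_rank_deficient_design(self):
        meta = SampleMetadata(
            np.arange(4.0), np.ones(4), np.ones((4, 1)), "gaussian"
        )
        with pytest.raises(ValueError, match="rank-deficient"):
            fit_null(meta)


class TestEndogenousKernels:
    def test_treatment_zero_and_one(self, rng):
        X = extract_surrogates(np.eye(5) + 0.1, "full")
        zero = build_endogenous(X, np.zeros(5))
        np.testing.assert_allclose(zero.kI, 0, atol=1e-14)
        np.testing.assert_allclose(zero.kB, zero.kM, atol=1e-14)
        one = build_endogenous(X, np.ones(5))
        np.testing.assert_allclose(one.kI, one.kM, atol=1e-14)
        np.testing.assert_allclose(one.kB, 2 * one.kM, atol=1e-14)

    def test_additivity_exact_and_concatenated_gram(self, rng):
        A = rng.normal(size=(7, 4))
        X = SurrogateVariants(A, np.linalg.norm(A, axis=0))
        T = rng.binomial(1, 0.5, 7).astype(float)
        ks = build_endogenous(X, T)
        assert np.array_equal(ks.kB, ks.kM + ks.kI)  # exact, not approximate
        concat = np.hstack([A, A * T[:, None]])
        np.testing.assert_allclose(ks.kB, concat @ concat.T, atol=1e-12)

    def test_interaction_entries(self, rng):
        A = rng.normal(size=(6, 3))
        X = SurrogateVariants(A, np.linalg.norm(A, axis=0))
        T = rng.normal(size=6)  # continuous treatment also allowed
        ks = build_endogenous(X, T)
        np.testing.assert_allclose(ks.kI, np.outer(T, T) * ks.kM, atol=1e-12)


class TestScoreStat:
    @pytest.mark.parametrize(
        "r,K,expected",
        [
            ([1.0, -1.0], np.eye(2), 2.0),
            ([1.0, -1.0], [[1.0, -1.0], [-1.0, 1.0]], 4.0),
            ([0.0, 0.0], np.eye(2), 0.0),
        ],
    )
    def test_hand_values(self, r, K, expected):
        assert score_stat(np.array(r), np.array(K)) == pytest.approx(expected)

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError, match="dimension"):
            score_stat(np.ones(3), np.eye(2))


class TestEmpiricalPvalues:
    def test_counting_definition(self):
        null = np.array([1.0, 2.0, 3.0, 4.0])
        assert empirical_pvalue(5.0, null) == 0.0
        assert empirical_pvalue(0.5, null) == 1.0
        assert empirical_pvalue(3.0, null) == 0.5  # ties count as >=

    def test_leave_one_out_hand_count(self):
        # null stats (1, 2, 3): for r'=1 both others are >=, p = 1.0
        loo = leave_one_out_pvalues(np.array([1.0, 2.0, 3.0]))
        np.testing.assert_allclose(loo, [1.0, 0.5, 0.0])

    def test_minp_observed_is_min(self):
        p = {"M": 0.2, "I": 0.5, "B": 0.9}
        loo = {t: np.array([0.1, 0.6]) for t in p}
        t_obs, _, _ = minp_single_kernel(p, loo)
        assert t_obs == 0.2


class TestPermutationPlan:
    def test_rows_are_permutations_and_reproducible(self):
        p1 = PermutationPlan.generate(8, 50, seed=3)
        p2 = PermutationPlan.generate(8, 50, seed=3)
        assert np.array_equal(p1.permutations, p2.permutations)
        assert not np.array_equal(
            p1.permutations, PermutationPlan.generate(8, 50, seed=4).permutations
        )

    def test_invalid_rows_rejected(self):
        with pytest.raises(ValueError, match="permutation"):
            PermutationPlan(np.array([[0, 0, 1]]))


@pytest.fixture
def exhaustive_setup(rng):
    """n=4 with all 24 permutations, generic continuous data (no ties)."""
    n = 4
    perms = np.array(list(itertools.permutations(range(n))))
    plan = PermutationPlan(perms)
    A = rng.normal(size=(n, 3))
    K = A @ A.T
    T = np.array([0.3, -1.2, 0.7, 2.1])
    y = rng.normal(size=n)
    meta = SampleMetadata(y, T, None, "gaussian")
    return K, meta, plan


class TestAgainstExhaustiveEnumeration:
    def test_identity_permutation_reproduces_observed(self, exhaustive_setup):
        K, meta, plan = exhaustive_setup
        res = single_kernel_test(K, fit_null(meta), meta.T, plan)
        idx = int(np.flatnonzero((plan.permutations == np.arange(4)).all(axis=1))[0])
        for t in ("M", "I", "B"):
            assert res.null_stats[t][idx] == pytest.approx(res.observed[t], rel=1e-12)

    def test_all_pvalues_match_naive_double_loop(self, exhaustive_setup):
        K, meta, plan = exhaustive_setup
        fit = fit_null(meta)
        res = single_kernel_test(K, fit, meta.T, plan)
        X = extract_surrogates(K, "full")
        ks = build_endogenous(X, meta.T)
        ref = naive_full_analysis(
            {"k": {"M": ks.kM, "I": ks.kI, "B": ks.kB}}, fit.residuals, list(plan.permutations)
        )["per_kernel"]["k"]
        for t in ("M", "I", "B"):
            assert res.pvalues[t] == ref["P"][t]
            np.testing.assert_array_equal(res.loo_pvalues[t], ref["loo"][t])
        assert res.t_minp == ref["t_minp"]
        np.testing.assert_array_equal(res.minp_null, ref["minp_null"])
        assert res.p_minp == ref["p_minp"]

    def test_constant_residuals_give_constant_null(self, exhaustive_setup):
        K, meta, plan = exhaustive_setup
        from omnik.kernel_association_test import NullModelFit

        r = np.full(4, 2.0)
        fit = NullModelFit("gaussian", np.zeros(2), np.zeros(4), r, np.ones((4, 2)))
        res = single_kernel_test(K, fit, np.ones(4), plan)
        for t in ("M", "I", "B"):
            np.testing.assert_allclose(res.null_stats[t], res.observed[t], rtol=1e-9)


class TestScaleInvariance:
    def test_pvalues_invariant_to_residual_scale(self, rng):
        """Rank-based: scaling residuals by c > 0 scales every quadratic form
        by c^2 and leaves all p-values unchanged."""
        n = 30
        plan = PermutationPlan.generate(n, 200, seed=5)
        A = rng.normal(size=(n, 6))
        K = A @ A.T
        T = rng.binomial(1, 0.5, n).astype(float)
        Z = rng.normal(size=(n, 1))
        y = rng.normal(size=n)
        meta1 = SampleMetadata(y, T, Z, "gaussian")
        meta2 = SampleMetadata(y * 7.3, T, Z, "gaussian")
        r1 = single_kernel_test(K, fit_null(meta1), T, plan)
        r2 = single_kernel_test(K, fit_null(meta2), T, plan)
        assert r1.pvalues == r2.pvalues
        assert r1.p_minp == r2.p_minp


class TestCountingProperties:
    """Property tests: the vectorized p-value machinery equals the counting
    definitions on arbitrary inputs, including ties."""

    from hypothesis import given, settings
    from hypothesis import strategies as st

    stat_lists = st.lists(
        st.floats(min_value=-10, max_value=10, allow_nan=False), min_size=2, max_size=40
    )

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(null=stat_lists, obs=st.floats(min_value=-10, max_value=10, allow_nan=False))
    def test_empirical_pvalue_counts(self, null, obs):
        null = np.asarray(null)
        expected = sum(v >= obs for v in null) / len(null)
        assert empirical_pvalue(obs, null) == expected

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(null=stat_lists)
    def test_leave_one_out_counts(self, null):
        null = np.asarray(null)
        R = len(null)
        got = leave_one_out_pvalues(null)
        for rp in range(R):
            expected = sum(null[r] >= null[rp] for r in range(R) if r != rp) / (R - 1)
            assert got[rp] == expected

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(null=stat_lists)
    def test_loo_pvalues_lie_on_rank_grid(self, null):
        loo = leave_one_out_pvalues(np.asarray(null))
        R = len(null)
        assert np.all((loo >= 0) & (loo <= 1))
        np.testing.assert_allclose(loo * (R - 1), np.round(loo * (R - 1)), atol=1e-9)
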