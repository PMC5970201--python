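import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cooccur import (
    SparCC,
    bh_adjust,
    permutation_pvalues,
    solve_basis,
    sparcc,
    sparcc_once,
    to_fractions,
    variation_matrix,
)
from cooccur.synthetic import null_scenario, planted_pair_scenario


class TestToFractions:
    def test_pseudocount_mode(self):
        frac = to_fractions(np.array([[0], [1]]), mode="pseudocount")
        np.testing.assert_allclose(frac.values[:, 0], [1 / 3, 2 / 3])

    def test_dirichlet_deterministic_for_fixed_seed(self):
        counts = np.array([[3, 0], [1, 9], [4, 4]])
        a = to_fractions(counts, seed=11).values
        b = to_fractions(counts, seed=11).values
        np.testing.assert_array_equal(a, b)

    def test_dirichlet_concentrates_at_large_counts(self):
        counts = np.array([[10**6], [10**6]])
        frac = to_fractions(counts, seed=0).values
        assert abs(frac[0, 0] - 0.5) < 0.01

    def test_output_strictly_positive_columns_sum_to_one(self):
        counts = np.zeros((5, 3), dtype=int)
        frac = to_fractions(counts, seed=1).values
        assert (frac > 0).all()
        np.testing.assert_allclose(frac.sum(axis=0), 1.0)


class TestVariationMatrix:
    def test_constant_fractions_give_zero(self):
        values = np.tile(np.array([[0.2], [0.3], [0.5]]), (1, 4))
        t = variation_matrix(values)
        np.testing.assert_allclose(t, 0.0, atol=1e-12)

    def test_two_sample_hand_value(self):
        # log-ratio of pair (0,1) equals (0, 2): variance with n−1 is 2
        values = np.array([[0.5, np.exp(2) / (1 + np.exp(2))],
                           [0.5, 1 / (1 + np.exp(2))]])
        values = values / values.sum(axis=0, keepdims=True)
        t = variation_matrix(values)
        assert t[0, 1] == pytest.approx(2.0)

    def test_symmetric_for_random_fractions(self):
        rng = np.random.default_rng(3)
        raw = rng.random((6, 10)) + 0.01
        values = raw / raw.sum(axis=0, keepdims=True)
        t = variation_matrix(values)
        np.testing.assert_allclose(t, t.T, atol=1e-12)

    def test_invariant_to_per_sample_rescaling(self):
        # the log-ratio kills any per-sample scale factor
        rng = np.random.default_rng(4)
        raw = rng.random((5, 8)) + 0.01
        scales = rng.random(8) + 0.5
        t1 = variation_matrix(raw / raw.sum(axis=0, keepdims=True))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            t2 = variation_matrix(raw * scales / (raw * scales).sum(axis=0, keepdims=True))
        # both are closures of the same composition, so identical
        np.testing.assert_allclose(t1, t2, atol=1e-10)


class TestSolveBasis:
    def test_three_component_worked_system(self):
        # t12=3, t13=4, t23=5: row sums (7,8,9); x_i + S = r_i with S = Σx = 6
        t = np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], dtype=float)
        with pytest.warns(UserWarning, match="d = 3"):
            est = solve_basis(t)
        np.testing.assert_allclose(est.omega_sq, [1.0, 2.0, 3.0], atol=1e-10)
        off = est.rho[np.triu_indices(3, 1)]
        np.testing.assert_allclose(off, 0.0, atol=1e-10)

    def test_zero_variation_matrix_degenerate(self):
        t = np.zeros((4, 4))
        with pytest.warns(UserWarning, match="floor"):
            est = solve_basis(t)
        assert est.degenerate
        np.testing.assert_allclose(est.rho, 1.0)

    def test_relabeling_invariance(self):
        rng = np.random.default_rng(0)
        raw = rng.random((5, 20)) + 0.01
        t = variation_matrix(raw / raw.sum(axis=0, keepdims=True))
        perm = rng.permutation(5)
        est = solve_basis(t)
        est_p = solve_basis(t[np.ix_(perm, perm)])
        np.testing.assert_allclose(est_p.omega_sq, est.omega_sq[perm], atol=1e-9)
        np.testing.assert_allclose(est_p.rho, est.rho[np.ix_(perm, perm)], atol=1e-9)

    @pytest.mark.parametrize("d", [4, 5, 6, 7, 8])
    def test_agrees_with_least_squares_oracle(self, d):
        """Build M=(d−2)I+1 by summing pair equations one at a time, solve by lstsq."""
        rng = np.random.default_rng(d)
        for _ in range(20):
            raw = rng.random((d, 15)) + 0.01
            t = variation_matrix(raw / raw.sum(axis=0, keepdims=True))
            m = np.zeros((d, d))
            b = np.zeros(d)
            for i in range(d):
                for j in range(d):
                    if i == j:
                        continue
                    # pair equation contribution: ω_i² + ω_j² ≈ t_ij added to row i
                    m[i, i] += 1.0
                    m[i, j] += 1.0
                    b[i] += t[i, j]
            omega_oracle, *_ = np.linalg.lstsq(m, b, rcond=None)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                est = solve_basis(t)
            # solve_basis floors tiny/negative variances; mirror that in the oracle
            omega_oracle = np.maximum(omega_oracle, 1e-12)
            assert np.max(np.abs(est.omega_sq - omega_oracle)) < 1e-8

    def test_excluded_pair_changes_system(self):
        rng = np.random.default_rng(9)
        raw = rng.random((6, 30)) + 0.01
        t = variation_matrix(raw / raw.sum(axis=0, keepdims=True))
        base = solve_basis(t)
        excl = solve_basis(t, excluded_pairs={(0, 1)})
        assert not np.allclose(base.omega_sq, excl.omega_sq)
        assert excl.excluded_pairs == {(0, 1)}


class TestSparccOnce:
    def test_no_exclusions_when_all_below_threshold(self):
        truth = null_scenario(n_otus=10, n_samples=40, seed=2)
        frac = to_fractions(truth.table.counts, seed=2)
        est_loop = sparcc_once(frac, n_exclusion_iter=10, exclusion_threshold=0.99)
        est_plain = solve_basis(variation_matrix(frac))
        np.testing.assert_allclose(est_loop.rho, est_plain.rho)
        assert est_loop.excluded_pairs == set()

    def test_zero_exclusion_iterations_equals_plain_solve(self):
        truth = planted_pair_scenario(seed=3)
        frac = to_fractions(truth.table.counts, seed=3)
        est0 = sparcc_once(frac, n_exclusion_iter=0)
        plain = solve_basis(variation_matrix(frac))
        np.testing.assert_allclose(est0.rho, plain.rho)

    def test_planted_pair_is_first_excluded(self):
        truth = planted_pair_scenario(r=0.9, seed=4)
        frac = to_fractions(truth.table.counts, seed=4)
        est = sparcc_once(frac, n_exclusion_iter=1, exclusion_threshold=0.1)
        assert (0, 1) in est.excluded_pairs


class TestSparcc:
    def test_copied_otu_recovered_with_high_correlation(self):
        truth = null_scenario(n_otus=29, n_samples=50, seed=5)
        counts = truth.table.counts
        # append an exact copy of OTU 0: basis correlation 1.0
        counts = np.vstack([counts, counts[0]])
        rho = sparcc(counts, seed=5)
        assert rho[0, 29] > 0.7

    def test_null_correlations_stay_small(self):
        truth = null_scenario(n_otus=30, n_samples=50, seed=6)
        rho = sparcc(truth.table, seed=6)
        off = np.abs(rho[np.triu_indices(30, 1)])
        assert np.percentile(off, 95) < 0.3

    def test_deterministic_for_fixed_seed(self):
        truth = null_scenario(n_otus=8, n_samples=25, seed=7)
        a = sparcc(truth.table, n_estimation_iter=5, seed=42)
        b = sparcc(truth.table, n_estimation_iter=5, seed=42)
        np.testing.assert_array_equal(a, b)

    def test_symmetric_unit_diagonal(self):
        truth = null_scenario(n_otus=6, n_samples=20, seed=8)
        rho = sparcc(truth.table, n_estimation_iter=5, seed=8)
        np.testing.assert_allclose(rho, rho.T)
        np.testing.assert_array_equal(np.diag(rho), 1.0)


class TestPermutationPvalues:
    def test_add_one_lower_bound_and_symmetry(self):
        truth = null_scenario(n_otus=6, n_samples=20, seed=9)
        rho = sparcc(truth.table, n_estimation_iter=5, seed=9)
        p = permutation_pvalues(truth.table, rho, n_permutations=20,
                                n_estimation_iter=2, seed=9)
        assert (p >= 1 / 21 - 1e-12).all()
        np.testing.assert_allclose(p, p.T)
        np.testing.assert_array_equal(np.diag(p), 1.0)

    def test_strongly_planted_pair_hits_the_floor(self):
        truth = planted_pair_scenario(r=0.9, n_otus=15, n_samples=50, seed=10)
        rho = sparcc(truth.table, seed=10)
        p = permutation_pvalues(truth.table, rho, n_permutations=100,
                                n_estimation_iter=3, seed=10)
        assert p[0, 1] == pytest.approx(1 / 101)

    def test_invalid_permutation_count(self):
        truth = null_scenario(n_otus=5, n_samples=10, seed=0)
        with pytest.raises(ValueError):
            permutation_pvalues(truth.table, np.eye(5), n_permutations=0)


class TestBHAdjust:
    def test_single_p_unchanged(self):
        np.testing.assert_allclose(bh_adjust(np.array([0.03])), [0.03])

    def test_hand_applied_step_up(self):
        q = bh_adjust(np.array([0.01, 0.02, 0.03, 0.04]))
        np.testing.assert_allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_rejects_out_of_range(self):
        for bad in ([0.0, 0.5], [0.5, 1.2]):
            with pytest.raises(ValueError):
                bh_adjust(np.array(bad))

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(min_value=1e-9, max_value=1.0), min_size=2, max_size=30))
    def test_monotone_and_never_below_input(self, pvals):
        p = np.array(pvals)
        q = bh_adjust(p)
        assert (q >= p - 1e-12).all()
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()


class TestSparCCEstimator:
    def test_sklearn_contract(self):
        est = SparCC(n_estimation_iter=3, random_state=0)
        params = est.get_params()
        assert params["n_estimation_iter"] == 3
        est.set_params(n_estimation_iter=4)
        assert est.get_params()["n_estimation_iter"] == 4

    def test_fit_sets_rho_and_significance(self):
        truth = null_scenario(n_otus=8, n_samples=30, seed=12)
        est = SparCC(
            n_estimation_iter=5, n_permutations=20,
            permutation_estimation_iter=2, random_state=12,
        ).fit(truth.table.counts.T)
        assert est.rho_.shape == (8, 8)
        assert est.n_features_in_ == 8
        assert (est.qvals_ >= est.pvals_ - 1e-12).all()
        result = est.result(otu_ids=truth.table.otu_ids)
        assert len(result.pair_table()) == 8 * 7 // 2

    def test_matches_functional_api(self):
        truth = null_scenario(n_otus=6, n_samples=25, seed=13)
        est = SparCC(n_estimation_iter=4, random_state=13).fit(truth.table.counts.T)
        direct = sparcc(truth.table, n_estimation_iter=4, seed=13)
        np.testing.assert_array_equal(est.rho_, direct)
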