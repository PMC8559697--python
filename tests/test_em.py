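"""Likelihoods, E-step expectations and single EM updates."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sigmixture import (
    MixParameters,
    mix_em_step,
    mix_log_likelihood,
    mix_responsibilities,
    mmm_expectations,
    mmm_log_likelihood,
)
from sigmixture.em import e_step

from conftest import random_catalog, random_params


class TestMMMLogLikelihood:
    def test_empty_counts_give_zero(self):
        assert mmm_log_likelihood([0, 0], [1.0], [[0.5, 0.5]]) == 0.0

    def test_uniform_single_signature(self):
        ll = mmm_log_likelihood([1, 1], [1.0], [[0.5, 0.5]])
        assert ll == pytest.approx(np.log(0.25), abs=1e-12)

    def test_two_signature_product(self):
        # per-category mixture probs: 0.6, 0.2, 0.2; counts (2, 1, 0)
        ll = mmm_log_likelihood([2, 1, 0], [0.6, 0.4], [[1, 0, 0], [0, 0.5, 0.5]])
        assert ll == pytest.approx(np.log(0.6**2 * 0.2), rel=1e-12)

    def test_structural_zero_with_positive_count_is_minus_inf(self):
        assert mmm_log_likelihood([0, 1], [1.0], [[1.0, 0.0]]) == -np.inf

    def test_dimension_mismatch_raises(self):
        with pytest.raises(ValueError):
            mmm_log_likelihood([1, 2, 3], [0.5, 0.5], [[0.5, 0.5], [0.5, 0.5]])

    def test_negative_counts_raise(self):
        with pytest.raises(ValueError):
            mmm_log_likelihood([-1, 1], [1.0], [[0.5, 0.5]])

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_matches_per_mutation_enumeration(self, seed):
        """The count-based likelihood equals the per-mutation product form."""
        rng = np.random.default_rng(seed)
        K, M = int(rng.integers(1, 4)), int(rng.integers(2, 5))
        pi = rng.dirichlet(np.ones(K))
        e = rng.dirichlet(np.ones(M), size=K)
        V = rng.integers(0, 3, size=M)
        mutations = np.repeat(np.arange(M), V)
        expected = sum(np.log(pi @ e[:, o]) for o in mutations)
        assert mmm_log_likelihood(V, pi, e) == pytest.approx(expected, abs=1e-10)


class TestMMMExpectations:
    def test_single_signature_takes_all_counts(self):
        V = np.array([3, 0, 2])
        E, A = mmm_expectations(V, [1.0], [[0.2, 0.3, 0.5]])
        np.testing.assert_allclose(E[0], V)
        assert A[0] == pytest.approx(5)

    def test_zero_count_categories_have_zero_expectation(self):
        E, _ = mmm_expectations([0, 4], [0.5, 0.5], [[0.5, 0.5], [0.5, 0.5]])
        np.testing.assert_allclose(E[:, 0], 0.0)

    def test_hand_worked_ratio(self):
        E, A = mmm_expectations([2, 1, 0], [0.6, 0.4], [[1, 0, 0], [0, 0.5, 0.5]])
        np.testing.assert_allclose(E, [[2, 0, 0], [0, 1, 0]], atol=1e-12)
        np.testing.assert_allclose(A, [2, 1], atol=1e-12)

    def test_expectations_partition_counts(self, rng):
        V = rng.integers(0, 9, size=5)
        pi = rng.dirichlet(np.ones(3))
        e = rng.dirichlet(np.ones(5), size=3)
        E, A = mmm_expectations(V, pi, e)
        np.testing.assert_allclose(E.sum(axis=0), V, atol=1e-10)
        np.testing.assert_allclose(A, E.sum(axis=1), atol=1e-12)

    def test_zero_probability_with_count_names_category(self):
        with pytest.raises(ValueError, match="category 1"):
            mmm_expectations([0, 2], [1.0], [[1.0, 0.0]])


class TestMixLogLikelihood:
    def test_single_cluster_reduces_to_mmm(self, rng):
        counts = rng.integers(0, 6, size=(4, 5))
        pi = rng.dirichlet(np.ones(2))
        e = rng.dirichlet(np.ones(5), size=2)
        params = MixParameters(w=np.array([1.0]), pi=pi[None, :], e=e)
        total = sum(mmm_log_likelihood(v, pi, e) for v in counts)
        assert mix_log_likelihood(counts, params) == pytest.approx(total, rel=1e-14)

    def test_duplicated_cluster_leaves_value_unchanged(self, rng):
        counts = rng.integers(0, 6, size=(4, 5))
        p1 = random_params(rng, 1, 2, 5)
        p2 = MixParameters(
            w=np.array([0.3, 0.7]), pi=np.vstack([p1.pi, p1.pi]), e=p1.e
        )
        assert mix_log_likelihood(counts, p2) == pytest.approx(
            mix_log_likelihood(counts, p1), rel=1e-12
        )

    def test_degenerate_two_cluster_instance(self, tiny_params):
        ll = mix_log_likelihood(np.array([[1, 0]]), tiny_params)
        assert ll == pytest.approx(np.log(0.5), rel=1e-14)

    def test_label_permutation_symmetry(self, rng):
        """Permuting clusters, or signatures jointly in pi and e, is a no-op."""
        counts = rng.integers(0, 6, size=(5, 4))
        p = random_params(rng, 3, 3, 4)
        ll = mix_log_likelihood(counts, p)
        perm_l = np.array([2, 0, 1])
        p_cl = MixParameters(w=p.w[perm_l], pi=p.pi[perm_l], e=p.e)
        assert mix_log_likelihood(counts, p_cl) == ll
        perm_k = np.array([1, 2, 0])
        p_sig = MixParameters(w=p.w, pi=p.pi[:, perm_k], e=p.e[perm_k])
        assert mix_log_likelihood(counts, p_sig) == ll

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_matches_brute_force_enumeration_on_tiny_instances(self, seed):
        """Mixture likelihood equals sum_l w_l prod_t sum_i pi^l_i e_i(o_t)."""
        rng = np.random.default_rng(seed)
        N, L, K, M = 3, int(rng.integers(1, 4)), int(rng.integers(1, 4)), 4
        p = random_params(rng, L, K, M)
        counts = rng.multinomial(int(rng.integers(0, 3)), np.ones(M) / M, size=N)
        expected = 0.0
        for v in counts:
            muts = np.repeat(np.arange(M), v)
            per_cluster = [
                p.w[l] * np.prod([p.pi[l] @ p.e[:, o] for o in muts])
                for l in range(L)
            ]
            expected += np.log(sum(per_cluster))
        assert mix_log_likelihood(counts, p) == pytest.approx(expected, abs=1e-10)


class TestMixResponsibilities:
    def test_identical_clusters_give_prior(self, rng):
        pi = rng.dirichlet(np.ones(2))
        p = MixParameters(
            w=np.array([0.3, 0.7]),
            pi=np.vstack([pi, pi]),
            e=rng.dirichlet(np.ones(4), size=2),
        )
        resp = mix_responsibilities(rng.integers(0, 5, size=(6, 4)), p)
        np.testing.assert_allclose(resp, np.tile(p.w, (6, 1)), atol=1e-12)

    def test_degenerate_prior(self, rng):
        p = random_params(rng, 2, 2, 4)
        p = MixParameters(w=np.array([1.0, 0.0]), pi=p.pi, e=p.e)
        resp = mix_responsibilities(rng.integers(0, 5, size=(6, 4)), p)
        np.testing.assert_allclose(resp, np.tile([1.0, 0.0], (6, 1)))

    def test_zero_likelihood_cluster_gets_zero_posterior(self, tiny_params):
        resp = mix_responsibilities(np.array([[1, 0]]), tiny_params)
        np.testing.assert_allclose(resp, [[1.0, 0.0]])

    def test_zero_mutation_sample_gets_prior(self, rng):
        p = random_params(rng, 3, 2, 4)
        resp = mix_responsibilities(np.zeros((1, 4), dtype=int), p)
        np.testing.assert_allclose(resp[0], p.w, atol=1e-12)

    def test_rows_sum_to_one(self, rng, small_catalog):
        p = random_params(rng, 4, 3, small_catalog.n_categories)
        resp = mix_responsibilities(small_catalog, p)
        np.testing.assert_allclose(resp.sum(axis=1), 1.0, atol=1e-9)

    def test_all_zero_likelihood_names_sample(self):
        p = MixParameters(
            w=np.array([1.0]), pi=np.array([[1.0]]), e=np.array([[1.0, 0.0]])
        )
        with pytest.raises(ValueError, match="sample 0"):
            mix_responsibilities(np.array([[0, 2]]), p)


class TestMixEMStep:
    def test_single_component_m_step_is_pooled_frequencies(self):
        counts = np.array([[2, 0], [1, 1]])
        p = MixParameters(
            w=np.array([1.0]), pi=np.array([[1.0]]), e=np.array([[0.4, 0.6]])
        )
        new, _, _ = mix_em_step(counts, p)
        np.testing.assert_allclose(new.e, [[0.75, 0.25]], atol=1e-12)
        np.testing.assert_allclose(new.pi, [[1.0]])
        np.testing.assert_allclose(new.w, [1.0])

    def test_refit_mode_freezes_signatures(self, rng, small_catalog):
        p = random_params(rng, 2, 3, small_catalog.n_categories)
        p = MixParameters(w=p.w, pi=p.pi, e=p.e, refit_mode=True)
        new, _, _ = mix_em_step(small_catalog, p)
        assert new.e is p.e  # bitwise identical: same object, never copied

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_monotone_likelihood(self, seed):
        rng = np.random.default_rng(seed)
        counts = random_catalog(rng, 5, 4).counts
        p = random_params(rng, 2, 2, 4)
        new, _, ll_before = mix_em_step(counts, p)
        assert mix_log_likelihood(counts, new) >= ll_before - 1e-9

    def test_sufficient_stats_conservation(self, rng, small_catalog):
        """W sums to N; A and E both sum to the total mutation count."""
        p = random_params(rng, 3, 2, small_catalog.n_categories)
        _, stats, _ = mix_em_step(small_catalog, p)
        total = small_catalog.counts.sum()
        assert stats.W.sum() == pytest.approx(small_catalog.n_samples, abs=1e-6)
        assert stats.A.sum() == pytest.approx(total, abs=1e-6)
        assert stats.E.sum() == pytest.approx(total, abs=1e-6)
        # pooled emissions match column totals category by category
        np.testing.assert_allclose(
            stats.E.sum(axis=0), small_catalog.counts.sum(axis=0), atol=1e-6
        )

    def test_new_params_satisfy_invariants(self, rng, small_catalog):
        p = random_params(rng, 3, 2, small_catalog.n_categories)
        new, _, _ = mix_em_step(small_catalog, p)  # validation runs in __post_init__
        assert new.w.sum() == pytest.approx(1.0, abs=1e-9)

    def test_starved_component_keeps_parameters_and_warns(self):
        p = MixParameters(
            w=np.array([1.0, 0.0]),
            pi=np.array([[1.0, 0.0], [0.0, 1.0]]),
            e=np.array([[0.5, 0.5], [0.2, 0.8]]),
        )
        with pytest.warns(RuntimeWarning):
            new, _, _ = mix_em_step(np.array([[3, 1]]), p)
        np.testing.assert_array_equal(new.pi[1], p.pi[1])


def test_e_step_weighted_rows_equal_repeated_rows(rng):
    """Collapsing duplicate samples with multiplicities changes no statistic."""
    row = rng.integers(0, 5, size=4)
    counts_rep = np.vstack([row, row, row, rng.integers(0, 5, size=4)])
    counts_uni = np.vstack([row, counts_rep[-1]])
    p = random_params(rng, 2, 2, 4)
    _, E1, A1, W1, ll1 = e_step(counts_rep, p.w, p.pi, p.e)
    _, E2, A2, W2, ll2 = e_step(
        counts_uni, p.w, p.pi, p.e, sample_weights=np.array([3.0, 1.0])
    )
    np.testing.assert_allclose(E1, E2, rtol=1e-12)
    np.testing.assert_allclose(A1, A2, rtol=1e-12)
    np.testing.assert_allclose(W1, W2, rtol=1e-12)
    assert ll1 == pytest.approx(ll2, rel=1e-12)
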