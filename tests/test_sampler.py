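"""Collapsed Gibbs sampler: seating law, predictive likelihood, chains."""

from __future__ import annotations

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from crpclust import (
    CategoricalDataset,
    ClusterState,
    Partition,
    SamplerConfig,
    gibbs_sweep,
    initialize_state,
    predictive_likelihood,
    prior_seating_probs,
    run_chain,
    seat_item,
    transfer_similarity,
)
from crpclust.synthetic import GeneratorConfig, generate
from conftest import crp_expected_clusters, eppf_probability


def two_group_dataset(n_per_group: int = 30) -> tuple[CategoricalDataset, Partition]:
    """Two blocks with disjoint deterministic response profiles."""
    d, v = 4, 3
    a = np.tile([0, 0, 0, 0], (n_per_group, 1))
    b = np.tile([2, 2, 2, 2], (n_per_group, 1))
    data = CategoricalDataset(np.vstack([a, b]), np.full(d, v))
    truth = Partition([0] * n_per_group + [1] * n_per_group)
    return data, truth


class TestPriorSeating:
    def test_worked_example(self):
        probs = prior_seating_probs([5, 2, 1], alpha=2.0)
        assert probs.tolist() == [0.5, 0.2, 0.1, 0.2]

    def test_no_tables_forces_new(self):
        assert prior_seating_probs([], alpha=3.0).tolist() == [1.0]

    def test_symmetric_tables(self):
        assert prior_seating_probs([1, 1], alpha=1.0) == pytest.approx([1 / 3] * 3)

    @given(
        st.lists(st.integers(1, 50), max_size=8),
        st.floats(0.01, 20.0, allow_nan=False),
    )
    @settings(deadline=None, derandomize=True)
    def test_always_normalized(self, sizes, alpha):
        probs = prior_seating_probs(sizes, alpha)
        assert probs.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.all(probs > 0)

    def test_rejects_invalid(self):
        with pytest.raises(ValueError):
            prior_seating_probs([2, 0], alpha=1.0)
        with pytest.raises(ValueError):
            prior_seating_probs([1], alpha=0.0)


class TestPredictiveLikelihood:
    def test_empty_cluster_is_prior_predictive(self):
        assert predictive_likelihood([0, 0], [3, 3]) == pytest.approx(1 / 9)

    def test_posterior_predictive_factor(self):
        counts = np.zeros((1, 3))
        counts[0] = [2, 0, 0]
        assert predictive_likelihood([0], [3], 1.0, counts, size=2) == pytest.approx(0.6)

    def test_rejects_out_of_range_code(self):
        with pytest.raises(ValueError):
            predictive_likelihood([3], [3])

    @pytest.mark.parametrize("category_counts", [(2,), (3, 2), (4, 3, 2)])
    def test_normalizes_over_all_response_vectors(self, category_counts, rng):
        v = np.asarray(category_counts)
        d = v.size
        counts = np.zeros((d, int(v.max())))
        size = 7
        for dim in range(d):
            counts[dim, : v[dim]] = rng.multinomial(size, np.ones(v[dim]) / v[dim])
        for beta, cl_counts, cl_size in [(1.0, None, 0), (0.5, counts, size), (2.0, counts, size)]:
            total = sum(
                predictive_likelihood(obs, v, beta, cl_counts, cl_size)
                for obs in itertools.product(*[range(x) for x in v])
            )
            assert total == pytest.approx(1.0, abs=1e-10)

    def test_matches_monte_carlo_dirichlet_integral(self, rng):
        # integral of prod_d theta_d[o_d] under the posterior Dirichlet
        v = np.array([3, 4])
        counts = np.zeros((2, 4))
        counts[0, :3] = [2, 1, 0]
        counts[1] = [1, 0, 2, 0]
        size, beta, obs = 3, 0.7, [0, 2]
        closed = predictive_likelihood(obs, v, beta, counts, size)
        draws = 40000
        est = np.ones(draws)
        for d in range(2):
            theta = rng.dirichlet(counts[d, : v[d]] + beta, size=draws)
            est *= theta[:, obs[d]]
        se = est.std(ddof=1) / np.sqrt(draws)
        assert abs(est.mean() - closed) < 3 * se + 1e-12


class TestSeating:
    def test_empty_state_founds_first_table(self, rng):
        data, _ = two_group_dataset(2)
        state = ClusterState(data)
        assert seat_item(0, state, SamplerConfig(), rng) == 0
        assert state.sizes.tolist() == [1]

    def test_tiny_alpha_joins_existing_cluster(self, rng):
        data, _ = two_group_dataset(2)
        cfg = SamplerConfig(alpha=1e-12)
        state = ClusterState(data)
        state.place_item(0, 0)
        for _ in range(50):
            if state.assignments[1] >= 0:
                state.remove_item(1)
            seat_item(1, state, cfg, rng)
        assert state.assignments[1] == 0

    def test_identical_clusters_get_equal_probability(self, rng):
        # two tables with the same counts and sizes must be exchangeable
        responses = np.array([[0], [0], [0], [0], [1]])
        data = CategoricalDataset(responses, [2])
        cfg = SamplerConfig()
        state = ClusterState(data)
        for i, k in [(0, 0), (1, 0), (2, 1), (3, 1)]:
            state.place_item(i, k)
        logw = state.seating_log_weights(4, cfg)
        assert logw[0] == pytest.approx(logw[1])
        counts = np.zeros(3, dtype=int)
        for _ in range(4000):
            state2_weights = state.seating_log_weights(4, cfg)
            w = np.exp(state2_weights - state2_weights.max())
            counts[rng.choice(3, p=w / w.sum())] += 1
        assert abs(counts[0] - counts[1]) < 4 * np.sqrt(counts[:2].sum())


class TestSweepAndChain:
    def test_sweep_preserves_invariants(self, rng):
        data, _ = two_group_dataset(10)
        cfg = SamplerConfig(burn_in=0, thinning=1, n_samples=1, n_chains=1)
        state = initialize_state(data, cfg, rng)
        for _ in range(5):
            gibbs_sweep(state, cfg, rng)
            assert state.n_seated == data.n
            state.check_invariants()

    def test_single_item_dataset(self, rng):
        data = CategoricalDataset(np.array([[1]]), [3])
        cfg = SamplerConfig()
        state = initialize_state(data, cfg, rng)
        gibbs_sweep(state, cfg, rng)
        assert state.partition().labels.tolist() == [0]

    def test_same_seed_same_chain(self):
        data, _ = two_group_dataset(8)
        cfg = SamplerConfig(burn_in=5, thinning=2, n_samples=10, n_chains=2, seed=42)
        a, b = run_chain(data, cfg), run_chain(data, cfg)
        assert all(
            np.array_equal(x.labels, y.labels)
            for x, y in zip(a.partitions, b.partitions)
        )
        assert np.array_equal(a.k_trace, b.k_trace)

    def test_chain_roundtrip_on_disk(self, tmp_path):
        data, _ = two_group_dataset(6)
        cfg = SamplerConfig(burn_in=2, thinning=1, n_samples=5, n_chains=2, seed=8)
        chain = run_chain(data, cfg)
        chain.save(tmp_path / "chain.jsonl")
        back = type(chain).load(tmp_path / "chain.jsonl")
        assert back.config == cfg
        assert np.array_equal(back.chain_ids, chain.chain_ids)
        assert all(
            x.is_equivalent(y) for x, y in zip(back.partitions, chain.partitions)
        )

    def test_config_validation(self):
        with pytest.raises(ValueError):
            SamplerConfig(alpha=0)
        with pytest.raises(ValueError):
            SamplerConfig(thinning=0)
        with pytest.raises(ValueError):
            SamplerConfig(n_samples=0)

    def test_recovers_two_separated_groups(self):
        data, truth = two_group_dataset(30)
        cfg = SamplerConfig(burn_in=20, thinning=2, n_samples=100, n_chains=1, seed=3)
        chain = run_chain(data, cfg)
        scores = [transfer_similarity(truth, p) for p in chain.partitions]
        assert np.mean(np.asarray(scores) >= 0.9) >= 0.95

    def test_prior_only_mean_cluster_count(self):
        # with the likelihood disabled the sweep targets the bare CRP, whose
        # mean cluster count is the harmonic-like sum alpha/(alpha+i)
        d, _ = two_group_dataset(30)  # 60 items; responses are ignored
        cfg = SamplerConfig(
            alpha=1.0, burn_in=20, thinning=2, n_samples=400, n_chains=1,
            seed=5, prior_only=True,
        )
        chain = run_chain(d, cfg)
        expected = crp_expected_clusters(d.n, 1.0)
        ks = chain.k_trace.astype(float)
        se = ks.std(ddof=1) / np.sqrt(ks.size)
        assert abs(ks.mean() - expected) < 4 * se

    def test_prior_only_initialization_matches_eppf(self, rng):
        # sequential prior-only seating must draw from the exact CRP
        # exchangeable partition distribution
        n, alpha, draws = 4, 1.0, 6000
        responses = np.zeros((n, 1), dtype=int)
        data = CategoricalDataset(responses, [2])
        cfg = SamplerConfig(alpha=alpha, prior_only=True)
        freq: dict[bytes, int] = {}
        for _ in range(draws):
            state = initialize_state(data, cfg, rng)
            key = state.partition().canonicalize().labels.tobytes()
            freq[key] = freq.get(key, 0) + 1
        from conftest import all_set_partitions

        for p in all_set_partitions(n):
            expected = eppf_probability(p, alpha)
            observed = freq.get(p.canonicalize().labels.tobytes(), 0) / draws
            se = np.sqrt(expected * (1 - expected) / draws)
            assert abs(observed - expected) < 4 * se
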