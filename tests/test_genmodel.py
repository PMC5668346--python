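"""Modularity oracle, competition ranking, model bookkeeping and diagnostics."""

import itertools

import numpy as np
import pytest

from diverseclub import (
    ModelConfig,
    WeightedGraph,
    competition_rank,
    detect,
    edge_objective,
    kld_fit,
    modularity_Q,
    run_model,
    run_null,
    stability_diagnostics,
)
from diverseclub.communities import Partition
from diverseclub.genmodel import StabilityReport
from .conftest import random_connected_graph


def brute_force_Q(g: WeightedGraph, membership, gamma=1.0) -> float:
    """Direct double summation of the configuration-null modularity.

    Runs over all ordered pairs: A_ii = 0, and the null term keeps its
    self-pair contribution as in the configuration model.
    """
    a = g.adjacency()
    k = a.sum(axis=1)
    two_m = a.sum()
    q = 0.0
    for i in range(g.n):
        for j in range(g.n):
            if membership[i] == membership[j]:
                q += a[i, j] - gamma * k[i] * k[j] / two_m
    return q / two_m


class TestModularity:
    def test_matches_brute_force_on_random_graphs(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            n = int(rng.integers(5, 13))
            g = random_connected_graph(rng, n, 0.4)
            if rng.random() < 0.5:  # weighted variant
                g = WeightedGraph(g.nodes, g.edges, rng.uniform(0.1, 2.0, g.m))
            mem = rng.integers(0, 3, size=n)
            gamma = float(rng.uniform(0.4, 1.5))
            p = Partition(graph=g, membership=mem)
            assert modularity_Q(g, p, gamma) == pytest.approx(
                brute_force_Q(g, p.membership, gamma), abs=1e-12
            )

    def test_two_disconnected_cliques_partitioned_by_clique(self):
        pairs = [(str(i), str(j)) for i in range(4) for j in range(i + 1, 4)]
        pairs += [(str(i), str(j)) for i in range(4, 8) for j in range(i + 1, 8)]
        g = WeightedGraph.from_edge_list(pairs)
        mem = np.array([0] * 4 + [1] * 4)
        p = Partition(graph=g, membership=mem)
        assert modularity_Q(g, p) == pytest.approx(brute_force_Q(g, mem), abs=1e-12)
        # two equal disconnected cliques: Q = 1 - 1/2
        assert modularity_Q(g, p) == pytest.approx(0.5)

    def test_random_partition_of_er_graph_near_zero(self):
        rng = np.random.default_rng(2)
        g = random_connected_graph(rng, 60, 0.15)
        mem = rng.integers(0, 4, size=60)
        assert abs(modularity_Q(g, Partition(graph=g, membership=mem))) < 0.1

    def test_gamma_zero_is_within_community_weight_fraction(self, two_cliques):
        mem = np.array([0] * 5 + [1] * 5)
        p = Partition(graph=two_cliques, membership=mem)
        frac = 20 / 21  # 20 intra edges of 21
        assert modularity_Q(two_cliques, p, gamma=0.0) == pytest.approx(frac)


class TestCompetitionRank:
    def test_documented_example(self):
        assert list(competition_rank([0.2, 0.5, 0.5, 0.9])) == [1, 2, 2, 4]

    def test_matches_enumeration_oracle(self):
        """Exhaustive check against a naive implementation on all integer
        vectors of length <= 6 over {0, 1, 2} (ties everywhere)."""

        def naive(xs):
            return [1 + sum(1 for y in xs if y < x) for x in xs]

        for length in range(1, 7):
            for xs in itertools.product((0, 1, 2), repeat=length):
                assert list(competition_rank(xs)) == naive(xs)


class TestCompetitionRankProperties:
    from hypothesis import given, settings
    from hypothesis import strategies as st

    @settings(deadline=None, derandomize=True, max_examples=200)
    @given(st.lists(st.integers(-5, 5), min_size=1, max_size=30))
    def test_rank_axioms(self, xs):
        """Min rank is 1, ties share a rank, distinct values order strictly."""
        ranks = competition_rank(xs)
        assert ranks.min() == 1
        for i, xi in enumerate(xs):
            for j, xj in enumerate(xs):
                if xi == xj:
                    assert ranks[i] == ranks[j]
                elif xi < xj:
                    assert ranks[i] < ranks[j]
            # competition ranking: rank = 1 + count of strictly smaller values
            assert ranks[i] == 1 + sum(1 for y in xs if y < xi)


class TestEdgeObjective:
    def _setup(self, seed=0):
        rng = np.random.default_rng(seed)
        g = random_connected_graph(rng, 40, 0.12)
        p = detect(g, "louvain", seed=1)
        return g, p

    def test_delta_q_matches_direct_recompute(self):
        g, p = self._setup()
        sc = edge_objective(g, p, 0.75)
        for ei in range(g.m):
            keep = np.ones(g.m, bool)
            keep[ei] = False
            g2 = WeightedGraph(g.nodes, g.edges[keep], g.weights[keep])
            direct = modularity_Q(
                g2, Partition(graph=g2, membership=p.membership)
            ) - modularity_Q(g, p)
            assert sc.delta_q[ei] == pytest.approx(direct, abs=1e-12)

    def test_delta_e_nonpositive_and_bridges_flagged(self):
        g, p = self._setup(3)
        sc = edge_objective(g, p, 0.75)
        assert np.all(sc.delta_e[~sc.is_bridge] <= 0)
        assert np.all(np.isnan(sc.delta_e[sc.is_bridge]))
        assert np.all(np.isneginf(sc.score[sc.is_bridge]))

    def test_q_ratio_one_orders_by_delta_q_ranks(self):
        g, p = self._setup(5)
        sc = edge_objective(g, p, 1.0)
        ok = ~sc.is_bridge
        ranks = competition_rank(sc.delta_q[ok])
        order_score = np.argsort(sc.score[ok], kind="stable")
        order_rank = np.argsort(ranks, kind="stable")
        assert np.array_equal(order_score, order_rank)

    def test_half_ratio_is_symmetric(self):
        g, p = self._setup(7)
        sc = edge_objective(g, p, 0.5)
        ok = ~sc.is_bridge
        zq = competition_rank(sc.delta_q[ok]).astype(float)
        ze = competition_rank(sc.delta_e[ok]).astype(float)
        zq = (zq - zq.mean()) / zq.std()
        ze = (ze - ze.mean()) / ze.std()
        assert np.allclose(sc.score[ok], 0.5 * zq + 0.5 * ze)


class TestRunModel:
    def test_default_bookkeeping(self):
        cfg = ModelConfig()
        assert cfg.m0 == 247
        assert cfg.batch_size == 13
        assert cfg.total_shuffled == 1950

    def test_trace_shapes_and_edge_conservation(self):
        cfg = ModelConfig(seed=11, iterations=20)
        tr = run_model(cfg)
        assert len(tr.Q_series) == 21 and len(tr.E_series) == 21
        assert tr.final_graph.m == cfg.m0
        assert tr.final_graph.is_connected()

    def test_reproducible_under_seed(self):
        cfg = ModelConfig(seed=4, iterations=10)
        a, b = run_model(cfg), run_model(cfg)
        assert np.array_equal(a.Q_series, b.Q_series)
        assert np.array_equal(a.final_graph.edges, b.final_graph.edges)

    def test_null_reproducible_and_conserves_edges(self):
        cfg = ModelConfig(seed=4, iterations=10)
        a, b = run_null(cfg), run_null(cfg)
        assert a.is_null and np.array_equal(a.E_series, b.E_series)
        assert a.final_graph.m == cfg.m0

    def test_selection_raises_q_above_null(self):
        """Short runs already separate selection from random shuffling."""
        cfg = ModelConfig(seed=21, iterations=60)
        tr = run_model(cfg)
        nu = run_null(ModelConfig(seed=21, iterations=60))
        assert tr.Q_series[-1] > tr.Q_series[0] + 0.1
        assert abs(nu.Q_series[-1] - nu.Q_series[0]) < 0.1


class TestStability:
    def _trace(self, q, e):
        return type(
            "T", (), {"Q_series": np.asarray(q, float), "E_series": np.asarray(e, float)}
        )()

    def test_constant_series_has_zero_change(self):
        tr = self._trace(np.ones(100), np.full(100, -5.0))
        rep = stability_diagnostics([tr], window_back=40, window_last=30)
        assert rep.q_change == 0.0 and rep.e_change == 0.0

    def test_doubling_series_change_vs_prior_value(self):
        x = 2.0 ** np.arange(80)
        tr = self._trace(x, -x)
        rep = stability_diagnostics([tr], window_back=1, window_last=30)
        assert rep.q_change == pytest.approx(100.0)  # doubles each step

    def test_short_series_rejected(self):
        tr = self._trace(np.ones(50), np.ones(50))
        with pytest.raises(ValueError, match="shorter"):
            stability_diagnostics([tr], window_back=40, window_last=30)

    def test_report_type(self):
        tr = self._trace(np.ones(100), np.ones(100))
        assert isinstance(stability_diagnostics([tr]), StabilityReport)


class TestKLD:
    def test_identical_vectors_zero(self):
        x = np.random.default_rng(0).normal(size=200)
        assert kld_fit(x, x) == 0.0

    def test_two_bin_closed_form(self):
        # P = [.5, .5], K = [.25, .75] over a shared 2-bin histogram
        p_vals = [0.0] * 2 + [1.0] * 2
        k_vals = [0.0] * 1 + [1.0] * 3
        expect = 0.5 * np.log(0.5 / 0.25) + 0.5 * np.log(0.5 / 0.75)
        assert kld_fit(p_vals, k_vals, bins=2) == pytest.approx(expect)

    def test_nonnegative(self):
        rng = np.random.default_rng(1)
        for _ in range(10):
            a, b = rng.normal(size=100), rng.normal(size=100)
            assert kld_fit(a, b) >= 0

    def test_empty_bin_in_reference_is_infinite(self):
        with pytest.warns(UserWarning, match="infinite"):
            v = kld_fit([0.0, 0.0, 10.0], [0.0, 0.1, 0.2], bins=2)
        assert np.isinf(v)

    def test_too_few_bins_rejected(self):
        with pytest.raises(ValueError, match="bins"):
            kld_fit([1.0], [1.0], bins=1)
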