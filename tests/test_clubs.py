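"""Club extraction, clubness, normalization, overlap, coverage, betweenness."""

import numpy as np
import pytest

from diverseclub import (
    NullEnsemble,
    WeightedGraph,
    club_betweenness,
    club_overlap,
    clubness,
    clubness_curve,
    community_coverage,
    detect,
    intra_club_edge_betweenness,
    make_club,
    normalized_clubness,
    participation_coefficient,
    randomize,
)
from diverseclub.communities import Partition


def _club_from(values, **kw):
    return make_club(values, **kw)


class TestMakeClub:
    def test_80th_percentile_of_264_distinct_values(self):
        values = {f"n{i}": float(i) for i in range(264)}
        club = _club_from(values, percentile=80)
        assert club.size == 53

    def test_rank_form_takes_top_n_minus_rank(self):
        values = {f"n{i}": float(i) for i in range(100)}
        club = _club_from(values, rank=85)
        assert club.size == 15
        assert min(float(v[1:]) for v in club.members) == 85.0

    def test_ties_at_cutoff_all_included(self):
        values = {"a": 1.0, "b": 2.0, "c": 2.0, "d": 2.0, "e": 3.0}
        club = _club_from(values, percentile=60)  # nominal 2 members
        assert club.size == 4  # the tie at 2.0 spans the cutoff

    def test_identical_values_rejected(self):
        with pytest.raises(ValueError, match="identical"):
            _club_from({"a": 1.0, "b": 1.0}, percentile=50)

    def test_percentile_bounds(self):
        values = {"a": 1.0, "b": 2.0}
        for bad in (0, 100, -5):
            with pytest.raises(ValueError):
                _club_from(values, percentile=bad)


class TestClubness:
    def test_clique_club_is_one(self, two_cliques):
        club = _club_from(
            {n: (1.0 if int(n) < 5 else 0.0) for n in two_cliques.nodes},
            percentile=50,
        )
        assert club.size == 5
        assert clubness(two_cliques, club) == pytest.approx(1.0)

    def test_partial_club(self):
        g = WeightedGraph.from_edge_list([("a", "b"), ("b", "c"), ("c", "d")])
        club = _club_from({"a": 3, "b": 2, "c": 1, "d": 0}, percentile=25)
        assert set(club.members) == {"a", "b", "c"}
        assert clubness(g, club) == pytest.approx(2 / 3)

    def test_empty_interior_gives_zero(self):
        g = WeightedGraph.from_edge_list([("a", "x"), ("b", "x"), ("c", "x")])
        club = _club_from({"a": 3, "b": 2, "c": 1.5, "x": 0}, percentile=25)
        assert clubness(g, club) == 0.0

    def test_singleton_rejected(self, two_cliques):
        from diverseclub import Club

        club = Club(metric="m", members=frozenset({"0"}), threshold_value=1.0,
                    universe=tuple(two_cliques.nodes))
        with pytest.raises(ValueError):
            clubness(two_cliques, club)

    def test_whole_set_theta_equals_density(self, planted):
        g, _ = planted
        club = _club_from({n: float(i) for i, n in enumerate(g.nodes)}, rank=0)
        assert club.size == g.n
        assert clubness(g, club) == pytest.approx(g.density)

    def test_adding_intra_edge_increases_theta(self, planted):
        g, _ = planted
        values = {n: float(i) for i, n in enumerate(g.nodes)}
        club = _club_from(values, percentile=80)
        members = sorted(club.members)
        idx = {n: i for i, n in enumerate(g.nodes)}
        present = {tuple(e) for e in g.edges}
        new = None
        for a in members:
            for b in members:
                key = tuple(sorted((idx[a], idx[b])))
                if a != b and key not in present:
                    new = key
                    break
            if new:
                break
        g2 = WeightedGraph(
            g.nodes,
            np.vstack([g.edges, new]),
            np.append(g.weights, 1.0),
        )
        assert clubness(g2, club) > clubness(g, club)


class TestNormalizedClubness:
    def test_self_ensemble_is_one(self, planted):
        g, _ = planted
        club = _club_from({n: float(i) for i, n in enumerate(g.nodes)}, percentile=80)
        ens = NullEnsemble(source=g, graphs=[g], mode="topology", seed=0)
        tn, _ = normalized_clubness(g, club, ens)
        assert tn == pytest.approx(1.0)

    def test_norm_above_one_iff_theta_above_null_mean(self, planted):
        g, _ = planted
        club = _club_from({n: float(i) for i, n in enumerate(g.nodes)}, percentile=80)
        ens = randomize(g, size=50, seed=0)
        tn, tsd = normalized_clubness(g, club, ens)
        thetas = [clubness(h, club) for h in ens.graphs]
        assert (tn > 1) == (clubness(g, club) > np.mean(thetas))

    def test_two_null_seeds_agree(self, bridge_fixture):
        """theta_norm from two independent null ensembles agrees within
        3 combined standard errors."""
        g, _ = bridge_fixture
        part = detect(g, "louvain", seed=0)
        pc = participation_coefficient(g, part)
        club = _club_from(dict(zip(g.nodes, pc)), percentile=80, metric="participation")
        theta = clubness(g, club)
        out = []
        for seed in (1, 2):
            ens = randomize(g, size=400, seed=seed)
            thetas = np.array([clubness(h, club) for h in ens.graphs])
            mean = thetas.mean()
            se = thetas.std(ddof=1) / np.sqrt(len(thetas))
            out.append((theta / mean, theta * se / mean**2))
        diff = abs(out[0][0] - out[1][0])
        combined = np.hypot(out[0][1], out[1][1])
        assert diff <= 3 * combined


class TestClubnessCurve:
    def test_lengths_and_sizes(self, planted):
        g, _ = planted
        ens = randomize(g, size=20, seed=0)
        values = dict(zip(g.nodes, map(float, range(g.n))))
        curve = clubness_curve(g, values, ens)
        assert len(curve.ranks) == g.n - 2
        assert np.all(curve.sizes[:-1] >= curve.sizes[1:])

    def test_matches_per_rank_make_club(self, planted):
        g, _ = planted
        rng = np.random.default_rng(0)
        values = dict(zip(g.nodes, rng.normal(size=g.n)))
        ens = randomize(g, size=5, seed=0)
        curve = clubness_curve(g, values, ens)
        for pos in (0, 10, 40, len(curve.ranks) - 1):
            club = make_club(values, rank=int(curve.ranks[pos]))
            assert curve.sizes[pos] == club.size
            assert curve.theta[pos] == pytest.approx(clubness(g, club))

    def test_diverse_beats_rich_on_bridge_fixture(self, bridge_fixture):
        """The designed high-PC bridge set is more interconnected than chance
        at top ranks, and more so than the rich club."""
        g, _ = bridge_fixture
        part = detect(g, "louvain", seed=0)
        pc = participation_coefficient(g, part)
        k = g.strength()
        ens = randomize(g, size=200, seed=1)
        div = clubness_curve(g, dict(zip(g.nodes, pc)), ens, metric="participation")
        rich = clubness_curve(g, dict(zip(g.nodes, k)), ens, metric="strength")
        top = slice(-10, None)
        assert np.nanmean(div.theta_norm[top]) > np.nanmean(rich.theta_norm[top])
        assert np.nanmean(div.theta_norm[top]) > 1.0

    def test_rank_zero_includes_everyone(self, planted):
        g, _ = planted
        ens = randomize(g, size=10, seed=0)
        values = dict(zip(g.nodes, map(float, range(g.n))))
        curve = clubness_curve(g, values, ens, ranks=[0])
        assert curve.sizes[0] == g.n
        # binary graph: whole-set theta equals density in source and nulls alike
        assert curve.theta_norm[0] == pytest.approx(1.0)


class TestOverlapCoverage:
    def test_identical_and_disjoint(self):
        values = {f"n{i}": float(i) for i in range(10)}
        a = _club_from(values, percentile=70)
        b = _club_from(values, percentile=70)
        assert club_overlap(a, b) == 100.0
        c = _club_from({k: -v for k, v in values.items()}, percentile=70)
        assert club_overlap(a, c) == 0.0

    def test_partial_overlap_ratio(self):
        universe = {f"n{i}": 0.0 for i in range(100)}
        a_vals = dict(universe)
        b_vals = dict(universe)
        for i in range(53):
            a_vals[f"n{i}"] = 1.0
        for i in range(41, 94):
            b_vals[f"n{i}"] = 1.0
        a = _club_from(a_vals, percentile=47)
        b = _club_from(b_vals, percentile=47)
        assert a.size == b.size == 53
        assert club_overlap(a, b) == pytest.approx(100 * 12 / 53)

    def test_coverage_counts_communities(self, planted):
        g, truth = planted
        # club confined to the first block only
        block0 = [n for n in g.nodes if n.startswith("b0_")]
        values = {n: (1.0 if n in block0 else 0.0) for n in g.nodes}
        club = _club_from(values, percentile=75)
        assert community_coverage(club, truth) == pytest.approx(100 / 4)


class TestBetweenness:
    def test_star_center_dominates(self, star_graph):
        club = _club_from(
            {"hub": 5.0, "leaf0": 1, "leaf1": 2, "leaf2": 3, "leaf3": 4}, rank=3
        )
        cmp_ = club_betweenness(star_graph, club)
        assert cmp_.values["hub"] == max(cmp_.values)
        assert cmp_.values["leaf0"] == 0.0

    def test_path_midpoint(self, path_graph):
        club = _club_from({"a": 1.0, "b": 3.0, "c": 2.0}, rank=1)
        cmp_ = club_betweenness(path_graph, club)
        assert cmp_.values["b"] == 1.0

    def test_bridge_edge_betweenness_highest(self, two_cliques):
        values = {n: (1.0 if n in ("4", "5") else 0.0) for n in two_cliques.nodes}
        club = _club_from(values, percentile=75)
        cmp_ = intra_club_edge_betweenness(two_cliques, club)
        ebt = cmp_.values
        assert ebt[("4", "5")] == ebt.max()  # the bridge carries all inter-clique paths

    def test_no_intra_edges_rejected(self, star_graph):
        club = _club_from(
            {"hub": 0.0, "leaf0": 1, "leaf1": 2, "leaf2": 3, "leaf3": 4}, rank=2
        )
        with pytest.raises(ValueError, match="no intra-club edges"):
            intra_club_edge_betweenness(star_graph, club)
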