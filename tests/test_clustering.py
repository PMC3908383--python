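"""Modularity, Qcut/HQcut, refinement operators and the rewiring null model."""

from itertools import combinations

import numpy as np
import networkx as nx
import pytest

from rwscomplex import (
    Network,
    Partition,
    community_pvalue,
    hqcut,
    modularity,
    qcut,
    refine,
    rewire_preserving_degrees,
    ring_of_cliques,
)


def brute_force_modularity(net: Network, assignment) -> float:
    """Independent per-edge summation oracle for Newman-Girvan Q."""
    W = sum(w for _, _, w in net.edges())
    inside = 0.0
    for u, v, w in net.edges():
        if assignment[u] == assignment[v]:
            inside += w
    strength = {n: 0.0 for n in net.nodes}
    for u, v, w in net.edges():
        strength[u] += w
        strength[v] += w
    comm_strength: dict = {}
    for n in net.nodes:
        comm_strength[assignment[n]] = comm_strength.get(assignment[n], 0.0) + strength[n]
    expected = sum((s / (2 * W)) ** 2 for s in comm_strength.values())
    return inside / W - expected


def random_weighted_net(n: int, p: float, seed: int) -> Network:
    rng = np.random.default_rng(seed)
    g = nx.gnp_random_graph(n, p, seed=seed)
    net = Network(nodes=[str(i) for i in range(n)])
    for u, v in g.edges:
        net.add_edge(str(u), str(v), float(rng.uniform(0.1, 3.0)))
    return net


class TestModularity:
    def test_single_community_is_zero(self, two_cliques_bridged):
        p = {n: 0 for n in two_cliques_bridged.nodes}
        assert modularity(two_cliques_bridged, p) == pytest.approx(0.0, abs=1e-15)

    def test_two_disjoint_cliques_half(self, two_cliques):
        p = {n: n[0] for n in two_cliques.nodes}
        assert modularity(two_cliques, p) == pytest.approx(0.5, abs=1e-15)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_oracle(self, seed):
        net = random_weighted_net(20, 0.25, seed)
        if net.total_weight() == 0:
            pytest.skip("degenerate draw")
        rng = np.random.default_rng(seed + 1000)
        assignment = {n: int(rng.integers(0, 4)) for n in net.nodes}
        assert modularity(net, assignment) == pytest.approx(
            brute_force_modularity(net, assignment), abs=1e-12
        )

    def test_zero_weight_errors(self):
        net = Network(nodes=["a", "b"])
        with pytest.raises(ValueError):
            modularity(net, {"a": 0, "b": 0})

    def test_uncovered_node_errors(self, triangle):
        with pytest.raises(ValueError):
            modularity(triangle, {"a": 0, "b": 0})


class TestQcut:
    def test_two_cliques_recovered_exactly(self, two_cliques):
        p = qcut(two_cliques)
        assert p.n_communities == 2
        assert p.q == pytest.approx(0.5)
        sides = {frozenset(m) for m in p.communities().values()}
        assert sides == {
            frozenset(f"x{i}" for i in range(5)),
            frozenset(f"y{i}" for i in range(5)),
        }

    def test_complete_graph_single_community(self):
        net = Network(edges=[(str(u), str(v)) for u, v in combinations(range(8), 2)])
        p = qcut(net)
        assert p.n_communities == 1
        assert p.q == pytest.approx(0.0, abs=1e-15)

    def test_isolated_nodes_are_singletons(self):
        net = Network(nodes=["iso1", "iso2"], edges=[("a", "b"), ("b", "c"), ("a", "c")])
        p = qcut(net)
        comms = p.communities()
        assert {tuple(m) for m in comms.values() if len(m) == 1} == {("iso1",), ("iso2",)}

    def test_deterministic(self, two_cliques_bridged):
        p1 = qcut(two_cliques_bridged, seed=5)
        p2 = qcut(two_cliques_bridged, seed=5)
        assert p1.assignment == p2.assignment and p1.q == p2.q

    @pytest.mark.parametrize("seed", range(5))
    def test_q_at_least_connected_components_baseline(self, seed):
        net = random_weighted_net(30, 0.1, seed)
        if net.n_edges < 2:
            pytest.skip("degenerate draw")
        p = qcut(net)
        assert -1.0 <= p.q <= 1.0
        # each community is internally connected or a singleton
        for members in p.communities().values():
            if len(members) > 1:
                sub = net.subgraph(members)
                assert len(sub.connected_components()) == 1


class TestRefine:
    def test_optimal_partition_is_fixed_point(self, two_cliques):
        opt = {n: n[0] for n in two_cliques.nodes}
        out = refine(two_cliques, opt)
        assert out.q == pytest.approx(0.5)
        groups = {frozenset(m) for m in out.communities().values()}
        assert len(groups) == 2

    def test_move_operator_restores_misassigned_vertex(self, two_cliques):
        bad = {n: n[0] for n in two_cliques.nodes}
        bad["x4"] = "y"  # misassign one vertex
        q_bad = modularity(two_cliques, bad)
        out = refine(two_cliques, bad)
        assert out.q > q_bad
        assert out.q == pytest.approx(0.5)

    def test_merge_operator_reunifies_oversplit_clique(self, two_cliques):
        split = {}
        for n in two_cliques.nodes:
            half = "h1" if n in {"x0", "x1"} else "h2"
            split[n] = n[0] if n.startswith("y") else half
        out = refine(two_cliques, split)
        assert out.q == pytest.approx(0.5)
        assert out.n_communities == 2

    @pytest.mark.parametrize("seed", range(5))
    def test_never_decreases_q(self, seed):
        net = random_weighted_net(25, 0.2, seed)
        if net.total_weight() == 0:
            pytest.skip("degenerate draw")
        rng = np.random.default_rng(seed)
        start = {n: int(rng.integers(0, 5)) for n in net.nodes}
        q0 = modularity(net, start)
        assert refine(net, start).q >= q0 - 1e-12


class TestRewire:
    def test_triangle_returns_triangle(self, triangle):
        out = rewire_preserving_degrees(triangle, seed=3)
        assert {frozenset((u, v)) for u, v, _ in out.edges()} == {
            frozenset(e) for e in [("a", "b"), ("b", "c"), ("a", "c")]
        }

    @pytest.mark.parametrize("seed", range(8))
    def test_degree_sequence_preserved_exactly(self, seed):
        net = random_weighted_net(30, 0.15, seed)
        if net.n_edges < 2:
            pytest.skip("degenerate draw")
        out = rewire_preserving_degrees(net, seed=seed)
        def degs(g):
            d = {n: 0 for n in g.nodes}
            for u, v, _ in g.edges():
                d[u] += 1
                d[v] += 1
            return sorted(d.values())
        assert degs(out) == degs(net)
        assert out.n_edges == net.n_edges  # no multi-edges or self-loops

    def test_weights_are_permuted(self):
        net = random_weighted_net(20, 0.3, seed=2)
        out = rewire_preserving_degrees(net, seed=7)
        assert sorted(w for _, _, w in out.edges()) == pytest.approx(
            sorted(w for _, _, w in net.edges())
        )

    def test_destroys_planted_structure(self):
        # rewired copies of a modular graph should be less modular
        from rwscomplex import SyntheticSpec, generate
        net, _ = generate(SyntheticSpec(n_complexes=6, size_range=(8, 8), seed=0))
        q_orig = qcut(net).q
        lower = sum(
            qcut(rewire_preserving_degrees(net, seed=s), seed=s).q < q_orig
            for s in range(10)
        )
        assert lower >= 8


class TestCommunityPvalue:
    def test_floor_when_no_null_exceeds(self, two_cliques_bridged):
        # observed Q of two bridged cliques far above any rewired null
        q_obs = qcut(two_cliques_bridged).q
        p = community_pvalue(two_cliques_bridged, q_obs, n_random=19, seed=0)
        assert p == pytest.approx(1 / 20)

    def test_q_obs_minus_one_gives_one(self, two_cliques_bridged):
        assert community_pvalue(two_cliques_bridged, -1.0, n_random=19, seed=0) == 1.0

    def test_tiny_subnet_never_significant(self, triangle):
        assert community_pvalue(triangle, 0.9, n_random=30, seed=0) == 1.0

    def test_random_graph_rarely_significant(self):
        # ER graphs lack real structure: their own Q is typical of the null
        hits = 0
        trials = 12
        for seed in range(trials):
            g = nx.gnp_random_graph(40, 0.3, seed=seed)
            net = Network(nodes=[str(i) for i in range(40)],
                          edges=[(str(u), str(v)) for u, v in g.edges])
            q_obs = qcut(net).q
            p = community_pvalue(net, q_obs, n_random=24, seed=seed)
            hits += p < 0.05
        assert hits <= trials // 3


class TestHQcut:
    def test_clique_communities_not_subdivided(self, two_cliques):
        p = hqcut(two_cliques, n_random=19, seed=0)
        assert p.n_communities == 2
        assert p.assignment == qcut(two_cliques).assignment

    def test_bridged_clique_pair_community_subdivided(self, two_cliques_bridged):
        # as a single community this has internal Q ~ 0.5 > 0.3, p < 0.05
        ring, _ = ring_of_cliques(6, 5)
        p = hqcut(ring, n_random=24, seed=1)
        for members in p.communities().values():
            prefixes = {m.split("N")[0] for m in members}
            assert len(prefixes) == 1  # no community spans two cliques

    def test_infinite_threshold_equals_qcut(self, two_cliques_bridged):
        ring, _ = ring_of_cliques(8, 4)
        assert (
            hqcut(ring, q_threshold=float("inf"), n_random=19, seed=0).assignment
            == qcut(ring).assignment
        )

    def test_partition_is_disjoint_exhaustive(self):
        net = random_weighted_net(40, 0.12, seed=4)
        p = hqcut(net, n_random=19, seed=2)
        assert set(p.assignment) == set(net.nodes)
        assert -1.0 <= p.q <= 1.0

    def test_deterministic_given_seed(self, two_cliques_bridged):
        ring, _ = ring_of_cliques(6, 4)
        p1 = hqcut(ring, n_random=19, seed=9)
        p2 = hqcut(ring, n_random=19, seed=9)
        assert p1.assignment == p2.assignment
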