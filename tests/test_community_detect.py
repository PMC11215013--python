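import itertools

import numpy as np
import pytest

from mpchg.community_detect import (
    Community,
    delta_fitness,
    detect_communities,
    fitness,
    merge_overlapping,
    overlap_degree,
)
from mpchg.hetero_graph import CompositeGraph


def make_graph(pair_edges, neighbor_edges=()):
    """Toy normalized graph from explicit weighted edge lists."""
    g = CompositeGraph()
    for u, v, w in pair_edges:
        g.nodes |= {u, v}
        g.pair_edges[(u, v)] = w
    for u, v, w in neighbor_edges:
        g.nodes |= {u, v}
        g.neighbor_edges[(u, v)] = w
    g.normalized = True
    g.total_weight = sum(w for *_, w in pair_edges) + sum(
        w for *_, w in neighbor_edges
    )
    g.avg_weight = g.total_weight / g.n_edges
    g._rebuild_adjacency()
    for km, side in g.nodes:
        target = g.neighbors_a if side == "A" else g.neighbors_b
        target.setdefault(km, {km})
    return g


def A(name):
    return (name, "A")


def B(name):
    return (name, "B")


@pytest.fixture
def square_graph():
    # 4 nodes in a cycle, 4 edges of weight 1 (alternating sides)
    return make_graph(
        [
            (A("a"), B("b"), 1.0),
            (A("c"), B("b"), 1.0),
            (A("c"), B("d"), 1.0),
            (A("a"), B("d"), 1.0),
        ]
    )


class TestFitness:
    def test_hand_value_on_square(self, square_graph):
        # S = 3 nodes with 2 internal edges: f = 2 - (1/8)*(6-4)*4 = 1
        s = {A("a"), B("b"), A("c")}
        assert fitness(s, square_graph) == pytest.approx(1.0)

    def test_empty_set_zero(self, square_graph):
        assert fitness(set(), square_graph) == 0.0

    def test_singleton_zero(self, square_graph):
        assert fitness({A("a")}, square_graph) == 0.0

    def test_clique_has_no_penalty(self):
        g = make_graph(
            [(A("a"), B("b"), 0.9), (A("a"), B("c"), 0.8)],
            [(B("b"), B("c"), 0.7)],
        )
        s = {A("a"), B("b"), B("c")}
        assert fitness(s, g) == pytest.approx(0.9 + 0.8 + 0.7)


def random_graph(rng, n_nodes):
    nodes = [A(f"a{i}") if i % 2 == 0 else B(f"b{i}") for i in range(n_nodes)]
    pair_edges, neighbor_edges = [], []
    for u, v in itertools.combinations(nodes, 2):
        if rng.random() < 0.5:
            w = float(rng.random())
            if u[1] != v[1]:
                ua, vb = (u, v) if u[1] == "A" else (v, u)
                pair_edges.append((ua, vb, w))
            else:
                neighbor_edges.append((u, v, w))
    if not pair_edges:
        pair_edges.append((A("a0"), B("b1"), 1.0))
    return make_graph(pair_edges, neighbor_edges)


class TestDeltaFitness:
    def test_incremental_equals_scratch_on_random_graphs(self, rng):
        for _ in range(100):
            g = random_graph(rng, int(rng.integers(4, 9)))
            nodes = sorted(g.nodes)
            size = int(rng.integers(1, len(nodes)))
            chosen = [nodes[i] for i in rng.choice(len(nodes), size, replace=False)]
            s = set(chosen)
            comm = Community(nodes=s, fitness=fitness(s, g))
            for v in g.nodes - s:
                delta = delta_fitness(comm, v, g)
                scratch = fitness(s | {v}, g) - fitness(s, g)
                assert delta == pytest.approx(scratch, abs=1e-9)

    def test_isolated_node_pure_penalty(self, square_graph):
        g = square_graph
        g.nodes.add(A("z"))
        g.adjacency[A("z")] = {}
        s = {A("a"), B("b")}
        comm = Community(nodes=s, fitness=fitness(s, g))
        expected = -g.total_weight / (2 * g.n_edges) * 2 * len(s)
        assert delta_fitness(comm, A("z"), g) == pytest.approx(expected)


class TestDetect:
    def test_two_far_apart_cliques(self):
        # two complete blocks (pair + neighbor edges), no cross edges:
        # every external candidate has delta <= 0, so each community
        # equals its clique
        pair, nbr = [], []
        for x1, x2, y1, y2 in [("a1", "a2", "b1", "b2"), ("c1", "c2", "d1", "d2")]:
            for xa in (x1, x2):
                for yb in (y1, y2):
                    pair.append((A(xa), B(yb), 0.9))
            nbr.append((A(x1), A(x2), 0.9))
            nbr.append((B(y1), B(y2), 0.9))
        g = make_graph(pair, nbr)
        core_a = {"a1", "a2", "c1", "c2"}
        core_b = {"b1", "b2", "d1", "d2"}
        comms = detect_communities(g, core_a, core_b)
        assert len(comms) == 2
        node_sets = sorted(tuple(sorted(c.nodes)) for c in comms)
        assert node_sets[0] == (A("a1"), A("a2"), B("b1"), B("b2"))
        assert node_sets[1] == (A("c1"), A("c2"), B("d1"), B("d2"))

    def test_single_seed_edge_no_growth(self):
        g = make_graph([(A("a"), B("b"), 1.0), (A("x"), B("y"), 0.1)])
        comms = detect_communities(g, {"a"}, {"b"})
        assert len(comms) == 1
        assert comms[0].nodes == {A("a"), B("b")}
        assert comms[0].seed_edge == (A("a"), B("b"))

    def test_no_core_pairs_empty(self, square_graph):
        assert detect_communities(square_graph, set(), set()) == []

    def test_communities_connected_and_contain_seed(self, rng):
        for _ in range(20):
            g = random_graph(rng, 8)
            core_a = {km for km, s in g.nodes if s == "A"}
            core_b = {km for km, s in g.nodes if s == "B"}
            for comm in detect_communities(g, core_a, core_b):
                assert set(comm.seed_edge) <= comm.nodes
                assert _connected(comm.nodes, g)
                assert comm.fitness == pytest.approx(
                    fitness(comm.nodes, g), abs=1e-9
                )

    def test_greedy_beats_bare_seed(self, rng):
        # sanity bound: grown community is at least as fit as its 2-node seed
        for _ in range(30):
            g = random_graph(rng, int(rng.integers(4, 9)))
            core_a = {km for km, s in g.nodes if s == "A"}
            core_b = {km for km, s in g.nodes if s == "B"}
            comms = detect_communities(g, core_a, core_b)
            if not comms:
                continue
            first = comms[0]
            assert first.fitness >= fitness(set(first.seed_edge), g) - 1e-12


def _connected(nodes, graph):
    nodes = set(nodes)
    start = next(iter(nodes))
    seen = {start}
    stack = [start]
    while stack:
        u = stack.pop()
        for v in graph.adjacency.get(u, {}):
            if v in nodes and v not in seen:
                seen.add(v)
                stack.append(v)
    return seen == nodes


class TestMerge:
    def _comm(self, names, graph):
        nodes = set(names)
        return Community(nodes=nodes, fitness=fitness(nodes, graph))

    def test_overlapping_pair_merged(self, square_graph):
        g = square_graph
        c1 = self._comm({A("a"), B("b"), A("c")}, g)
        c2 = self._comm({B("b"), A("c"), B("d")}, g)
        merged = merge_overlapping([c1, c2], g)
        assert len(merged) == 1
        assert merged[0].nodes == {A("a"), B("b"), A("c"), B("d")}
        assert merged[0].fitness == pytest.approx(fitness(merged[0].nodes, g))

    def test_disjoint_untouched(self, square_graph):
        c1 = self._comm({A("a"), B("b")}, square_graph)
        c2 = self._comm({A("c"), B("d")}, square_graph)
        assert len(merge_overlapping([c1, c2], square_graph)) == 2

    def test_exactly_half_overlap_not_merged(self, square_graph):
        c1 = self._comm({A("a"), B("b")}, square_graph)
        c2 = self._comm({B("b"), A("c")}, square_graph)
        assert overlap_degree(c1, c2) == pytest.approx(0.5)
        assert len(merge_overlapping([c1, c2], square_graph)) == 2

    def test_pairwise_overlap_bounded_after_merge(self, rng):
        for _ in range(20):
            g = random_graph(rng, 8)
            nodes = sorted(g.nodes)
            comms = []
            for _ in range(4):
                size = int(rng.integers(2, len(nodes) + 1))
                chosen = [nodes[i] for i in rng.choice(len(nodes), size, replace=False)]
                comms.append(Community(set(chosen), fitness(set(chosen), g)))
            merged = merge_overlapping(comms, g)
            for c1, c2 in itertools.combinations(merged, 2):
                assert overlap_degree(c1, c2) <= 0.5
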