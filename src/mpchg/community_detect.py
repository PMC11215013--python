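"""Dense-subgraph mining by greedy fitness maximization.

The fitness of a node set S compares the weight of its internal edges
with the weight the same number of node pairs would carry if every
missing edge were filled in at the graph's average edge weight:

    f(S) = sum_{e in S} w(e) - (1 / (2|E|)) * (n_S(n_S - 1) - 2 m_S) * sum_{e in G} w(e)

Communities are seeded from the heaviest unassigned core pair edge and
grown one node at a time while the fitness gain is positive; overlapping
communities (> 0.5 overlap degree) are merged afterwards.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from mpchg.hetero_graph import CompositeGraph, Node

log = logging.getLogger(__name__)


@dataclass
class Community:
    """A dense subgraph with its fitness and internal pair-edge weights."""

    nodes: set[Node]
    fitness: float
    pair_weights: dict[tuple[Node, Node], float] = field(default_factory=dict)
    seed_edge: tuple[Node, Node] | None = None

    def __len__(self) -> int:
        return len(self.nodes)


def fitness(node_set: set[Node], graph: CompositeGraph) -> float:
    """Recompute f(S) from scratch on a node set."""
    if not node_set:
        return 0.0
    internal = 0.0
    m_s = 0
    for (u, v), w in graph.edges().items():
        if u in node_set and v in node_set:
            internal += w
            m_s += 1
    n_s = len(node_set)
    penalty = (n_s * (n_s - 1) - 2 * m_s) * graph.total_weight / (2 * graph.n_edges)
    return internal - penalty


def delta_fitness(community: Community, v: Node, graph: CompositeGraph) -> float:
    """Fitness gain of adding node v, in incremental form.

    Equals f(S + v) - f(S): the weight of v's edges into S minus the
    graph's average edge weight times the number of S-members v is not
    connected to.
    """
    w_in = 0.0
    deg = 0
    for u, w in graph.adjacency.get(v, {}).items():
        if u in community.nodes:
            w_in += w
            deg += 1
    return w_in - graph.avg_weight * (len(community.nodes) - deg)


def _node_neighbor_count(graph: CompositeGraph, node: Node) -> int:
    km, side = node
    nbrs = graph.neighbors_a if side == "A" else graph.neighbors_b
    return len(nbrs.get(km, {km}))


def _grow(seed: tuple[Node, Node], graph: CompositeGraph) -> Community:
    a, b = seed
    nodes = {a, b}
    # candidate -> (weight into S, degree into S), kept incrementally
    cand: dict[Node, list] = {}

    def absorb(new_node: Node) -> None:
        for u, w in graph.adjacency[new_node].items():
            if u in nodes:
                continue
            entry = cand.setdefault(u, [0.0, 0])
            entry[0] += w
            entry[1] += 1

    f = graph.adjacency[a].get(b, 0.0)  # seed edge weight; internal fitness
    absorb(a)
    absorb(b)
    cand.pop(a, None)
    cand.pop(b, None)
    while cand:
        n_s = len(nodes)
        best_node = None
        best_delta = 0.0
        for u in sorted(cand):  # lexicographic tie-break via ordered scan
            w_in, deg = cand[u]
            delta = w_in - graph.avg_weight * (n_s - deg)
            if delta > best_delta + 1e-12 or (
                best_node is None and delta > 1e-12
            ):
                best_node = u
                best_delta = delta
        if best_node is None:
            break
        nodes.add(best_node)
        f += best_delta
        w_in, _ = cand.pop(best_node)
        absorb(best_node)
    comm = Community(nodes=nodes, fitness=f, seed_edge=seed)
    comm.pair_weights = {
        e: w
        for e, w in graph.pair_edges.items()
        if e[0] in nodes and e[1] in nodes
    }
    return comm


def detect_communities(
    graph: CompositeGraph, core_a: set[str], core_b: set[str]
) -> list[Community]:
    """Seed-and-grow community detection from core pair edges.

    Seeds are taken greedily: the maximum-weight pair edge whose two
    endpoints are both core k-mers and not yet assigned to any community
    (ties broken by total endpoint neighbor count, then lexicographic).
    Growth adds the adjacent node with the largest positive fitness gain.
    Nodes that end up in no community are dropped as isolated points.
    """
    if not graph.normalized:
        raise ValueError("graph must be normalized before community detection")
    core_edges = [
        (edge, w)
        for edge, w in graph.pair_edges.items()
        if edge[0][0] in core_a and edge[1][0] in core_b
    ]
    if not core_edges:
        log.warning("no core pair edges; no communities detected")
        return []

    def seed_rank(item):
        (na, nb), w = item
        return (
            w,
            _node_neighbor_count(graph, na) + _node_neighbor_count(graph, nb),
            # invert lexicographic order so max() prefers the smaller pair
            tuple(-ord(c) for c in na[0] + nb[0]),
        )

    assigned: set[Node] = set()
    communities: list[Community] = []
    remaining = list(core_edges)
    while True:
        remaining = [
            (e, w)
            for e, w in remaining
            if e[0] not in assigned and e[1] not in assigned
        ]
        if not remaining:
            break
        seed_edge = max(remaining, key=seed_rank)[0]
        comm = _grow(seed_edge, graph)
        scratch = fitness(comm.nodes, graph)
        assert abs(comm.fitness - scratch) < 1e-9 * max(1.0, abs(scratch)) + 1e-9
        communities.append(comm)
        assigned |= comm.nodes
    log.info("detected %d communities before merging", len(communities))
    return communities


def overlap_degree(c1: Community, c2: Community) -> float:
    return len(c1.nodes & c2.nodes) / min(len(c1), len(c2))


def merge_overlapping(
    communities: list[Community],
    graph: CompositeGraph,
    threshold: float = 0.5,
) -> list[Community]:
    """Merge community pairs whose overlap degree strictly exceeds threshold.

    The most-overlapping pair is merged first and overlaps recomputed;
    terminates because the community count strictly decreases.
    """
    comms = list(communities)
    while len(comms) > 1:
        best = None
        best_ov = threshold
        for i in range(len(comms)):
            for j in range(i + 1, len(comms)):
                ov = overlap_degree(comms[i], comms[j])
                if ov > best_ov:
                    best_ov = ov
                    best = (i, j)
        if best is None:
            break
        i, j = best
        merged_nodes = comms[i].nodes | comms[j].nodes
        merged = Community(
            nodes=merged_nodes,
            fitness=fitness(merged_nodes, graph),
            seed_edge=comms[i].seed_edge,
        )
        merged.pair_weights = {
            e: w
            for e, w in graph.pair_edges.items()
            if e[0] in merged_nodes and e[1] in merged_nodes
        }
        comms = [c for idx, c in enumerate(comms) if idx not in (i, j)] + [merged]
    return comms
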