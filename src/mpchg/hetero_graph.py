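"""Composite heterogeneous k-mer graph construction.

Nodes are significant canonical k-mers, typed by side. Two edge types:

* pair edges between an A-side and a B-side k-mer that co-occur in at
  least one sequence pair, weighted by min-max-scaled co-occurrence plus
  the two endpoints' neighbor fractions;
* neighborhood edges between same-side k-mers related by one mismatch or
  a suffix-prefix overlap of at least 4 bases, weighted by the overlap of
  their neighbor sets.

All weights are finally min-max normalized jointly to [0, 1].
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from itertools import combinations

from mpchg.kmer_stats import KmerCatalog

log = logging.getLogger(__name__)

Node = tuple[str, str]  # (kmer, side)


class GraphError(ValueError):
    pass


def overlap_shifts(kmer1: str, kmer2: str, min_overlap: int = 4) -> list[tuple[int, int]]:
    """All suffix-prefix alignments between two equal-length k-mers.

    Returns (shift, overlap_length) pairs where `shift` is the offset of
    kmer2 relative to kmer1 (positive: kmer2 starts to the right) and the
    overlapping region matches exactly with length >= min_overlap.
    Shift 0 (identity) is excluded.
    """
    if len(kmer1) != len(kmer2):
        raise ValueError("k-mers must have equal length")
    k = len(kmer1)
    out = []
    for shift in range(1, k - min_overlap + 1):
        if kmer1[shift:] == kmer2[: k - shift]:
            out.append((shift, k - shift))
        if kmer2[shift:] == kmer1[: k - shift]:
            out.append((-shift, k - shift))
    return out


def is_neighbor(kmer1: str, kmer2: str) -> bool:
    """Neighbor relation: Hamming distance 1, or overlap >= 4 bases."""
    if len(kmer1) != len(kmer2):
        raise ValueError("k-mers must have equal length")
    if kmer1 == kmer2:
        return False
    if sum(a != b for a, b in zip(kmer1, kmer2)) == 1:
        return True
    return bool(overlap_shifts(kmer1, kmer2))


def neighbor_sets(kmers: set[str] | frozenset[str]) -> dict[str, set[str]]:
    """L(v) for every k-mer: its neighbors within the set, including itself.

    Uses hashing on 1-mismatch masks and on prefixes/suffixes, so the
    cost is O(n * k) rather than O(n^2).
    """
    kmers = set(kmers)
    sets: dict[str, set[str]] = {km: {km} for km in kmers}
    if not kmers:
        return sets
    k = len(next(iter(kmers)))
    # Hamming distance 1: bucket by k-mer with one masked position.
    for pos in range(k):
        buckets: dict[str, list[str]] = {}
        for km in kmers:
            buckets.setdefault(km[:pos] + km[pos + 1 :], []).append(km)
        for group in buckets.values():
            for a, b in combinations(group, 2):
                sets[a].add(b)
                sets[b].add(a)
    # suffix-prefix overlap >= 4
    for ov in range(4, k):
        prefix: dict[str, list[str]] = {}
        for km in kmers:
            prefix.setdefault(km[:ov], []).append(km)
        for km in kmers:
            for other in prefix.get(km[k - ov :], ()):
                if other != km:
                    sets[km].add(other)
                    sets[other].add(km)
    return sets


def pair_edge_weight(
    n_cooc: int, n_min: int, n_max: int, l_v: int, n_e: int, l_u: int, m_tss: int
) -> float:
    """Raw pair-edge weight: scaled co-occurrence + neighbor fractions."""
    scaled = 0.0 if n_max == n_min else (n_cooc - n_min) / (n_max - n_min)
    return scaled + l_v / n_e + l_u / m_tss


def neighbor_edge_weight(n_common: int, l_p: int, l_q: int) -> float:
    """Raw neighborhood-edge weight: shared-neighbor fractions."""
    return n_common / l_p + n_common / l_q


@dataclass
class CompositeGraph:
    """Typed k-mer graph with pair and neighborhood edges.

    Edge keys are canonical: pair edges as ((kmer_a, 'A'), (kmer_b, 'B')),
    neighbor edges with endpoints in lexicographic order.
    """

    nodes: set[Node] = field(default_factory=set)
    pair_edges: dict[tuple[Node, Node], float] = field(default_factory=dict)
    neighbor_edges: dict[tuple[Node, Node], float] = field(default_factory=dict)
    cooc_counts: dict[tuple[Node, Node], int] = field(default_factory=dict)
    neighbors_a: dict[str, set[str]] = field(default_factory=dict)
    neighbors_b: dict[str, set[str]] = field(default_factory=dict)
    n_e: int = 0
    m_tss: int = 0
    n_min: int = 0
    n_max: int = 0
    normalized: bool = False
    # filled by normalize_weights
    total_weight: float = 0.0
    avg_weight: float = 0.0
    adjacency: dict[Node, dict[Node, float]] = field(default_factory=dict)

    def edges(self) -> dict[tuple[Node, Node], float]:
        merged = dict(self.pair_edges)
        merged.update(self.neighbor_edges)
        return merged

    @property
    def n_edges(self) -> int:
        return len(self.pair_edges) + len(self.neighbor_edges)

    def _rebuild_adjacency(self) -> None:
        adj: dict[Node, dict[Node, float]] = {n: {} for n in self.nodes}
        for (u, v), w in self.edges().items():
            adj[u][v] = w
            adj[v][u] = w
        self.adjacency = adj


def build_pair_edges(
    catalog_a: KmerCatalog,
    catalog_b: KmerCatalog,
    n_pairs: int | None = None,
    cooc_z_threshold: float | None = 1.96,
) -> CompositeGraph:
    """Connect cross-side k-mers that co-occur in sequence pairs.

    Co-occurrence counts distinct pair ids (multiplicity within one
    sequence does not add), derived from the catalogs' occurrence maps
    recorded at enumeration time.

    With frequent k-mers on long sequences, almost every cross-side pair
    co-occurs somewhere by chance, which would make the graph near
    complete-bipartite and chance edges indistinguishable from motif
    structure. `cooc_z_threshold` therefore applies the same background
    logic used for nodes to the edges: an edge is kept only when its
    count exceeds the expectation under independent presence of the two
    k-mers (binomial one-sided z above the threshold, defaulting to the
    method's 1.96). Pass None to keep every edge with count >= 1.
    """
    if not catalog_a.records or not catalog_b.records:
        raise GraphError("empty graph: a side has no significant k-mers")
    if cooc_z_threshold is not None and n_pairs is None:
        raise ValueError("n_pairs is required for the co-occurrence z filter")
    nbr_a = neighbor_sets(set(catalog_a.records))
    nbr_b = neighbor_sets(set(catalog_b.records))
    n_e = len(catalog_a.records)
    m_tss = len(catalog_b.records)

    # bitmask co-occurrence: pair_id -> bit, presence as big ints
    all_ids: dict[str, int] = {}
    masks_a: dict[str, int] = {}
    masks_b: dict[str, int] = {}
    for cat, masks in ((catalog_a, masks_a), (catalog_b, masks_b)):
        for km, rec in cat.records.items():
            m = 0
            for pid in rec.occurrences:
                bit = all_ids.setdefault(pid, len(all_ids))
                m |= 1 << bit
            masks[km] = m

    counts: dict[tuple[Node, Node], int] = {}
    for ka, ma in masks_a.items():
        node_a = (ka, "A")
        pa = ma.bit_count() / n_pairs if n_pairs else 0.0
        for kb, mb in masks_b.items():
            n = (ma & mb).bit_count()
            if n < 1:
                continue
            if cooc_z_threshold is not None:
                q = pa * (mb.bit_count() / n_pairs)
                sd = math.sqrt(n_pairs * q * (1.0 - q))
                if sd == 0.0 or (n - n_pairs * q) / sd <= cooc_z_threshold:
                    continue
            counts[(node_a, (kb, "B"))] = n
    if not counts:
        raise GraphError("empty graph: no co-occurring k-mer pairs")
    n_min = min(counts.values())
    n_max = max(counts.values())
    graph = CompositeGraph(
        nodes={(km, "A") for km in catalog_a.records}
        | {(km, "B") for km in catalog_b.records},
        cooc_counts=counts,
        neighbors_a=nbr_a,
        neighbors_b=nbr_b,
        n_e=n_e,
        m_tss=m_tss,
        n_min=n_min,
        n_max=n_max,
    )
    for ((ka, _), (kb, _)), n in counts.items():
        graph.pair_edges[((ka, "A"), (kb, "B"))] = pair_edge_weight(
            n, n_min, n_max, len(nbr_a[ka]), n_e, len(nbr_b[kb]), m_tss
        )
    return graph


def build_neighbor_edges(graph: CompositeGraph) -> CompositeGraph:
    """Add same-side edges between neighboring k-mers (Jaccard-like weight)."""
    for side, nbrs in (("A", graph.neighbors_a), ("B", graph.neighbors_b)):
        for km, l_p in nbrs.items():
            for other in l_p:
                if other <= km:  # each unordered pair once; skips self
                    continue
                l_q = nbrs[other]
                common = len(l_p & l_q)
                graph.neighbor_edges[((km, side), (other, side))] = (
                    neighbor_edge_weight(common, len(l_p), len(l_q))
                )
    return graph


def normalize_weights(graph: CompositeGraph) -> CompositeGraph:
    """Min-max scale all edge weights jointly to [0, 1].

    Degenerate case (all weights equal) maps every weight to 1 so the
    edges stay usable downstream.
    """
    if graph.n_edges == 0:
        raise GraphError("cannot normalize a graph with no edges")
    weights = list(graph.pair_edges.values()) + list(graph.neighbor_edges.values())
    w_min, w_max = min(weights), max(weights)
    if w_max == w_min:
        scale = lambda w: 1.0  # noqa: E731
    else:
        scale = lambda w: (w - w_min) / (w_max - w_min)  # noqa: E731
    for key in graph.pair_edges:
        graph.pair_edges[key] = scale(graph.pair_edges[key])
    for key in graph.neighbor_edges:
        graph.neighbor_edges[key] = scale(graph.neighbor_edges[key])
    graph.normalized = True
    graph.total_weight = sum(graph.pair_edges.values()) + sum(
        graph.neighbor_edges.values()
    )
    graph.avg_weight = graph.total_weight / graph.n_edges
    graph._rebuild_adjacency()
    return graph


def build_graph(
    catalog_a: KmerCatalog,
    catalog_b: KmerCatalog,
    n_pairs: int | None = None,
    cooc_z_threshold: float | None = 1.96,
) -> CompositeGraph:
    """Full construction: pair edges, neighbor edges, joint normalization."""
    graph = build_pair_edges(catalog_a, catalog_b, n_pairs, cooc_z_threshold)
    graph = build_neighbor_edges(graph)
    graph = normalize_weights(graph)
    log.info(
        "graph: %d nodes (%d A, %d B), %d pair edges, %d neighbor edges",
        len(graph.nodes),
        graph.n_e,
        graph.m_tss,
        len(graph.pair_edges),
        len(graph.neighbor_edges),
    )
    return graph


def write_edge_tsv(graph: CompositeGraph, raw_graph_edges, path) -> None:
    """Dump the edge list as TSV: src, dst, edge_type, raw_weight, norm_weight."""
    with open(path, "w") as fh:
        fh.write("src\tdst\tside_src\tside_dst\tedge_type\traw_weight\tnorm_weight\n")
        for etype, edges in (("pair", graph.pair_edges), ("neighbor", graph.neighbor_edges)):
            for ((ka, sa), (kb, sb)), w in sorted(edges.items()):
                raw = raw_graph_edges.get(((ka, sa), (kb, sb)), float("nan"))
                fh.write(f"{ka}\t{kb}\t{sa}\t{sb}\t{etype}\t{raw:.6g}\t{w:.6g}\n")
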