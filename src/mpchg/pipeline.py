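"""End-to-end orchestration: background, k-mer stats, graph, communities, motifs."""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, asdict, field
from pathlib import Path

from mpchg import community_detect, hetero_graph, kmer_stats, motif_assembly, seq_io

log = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage produced an empty or invalid result; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")


@dataclass
class PipelineConfig:
    """All tunable thresholds of a run, with the method's defaults."""

    k: int = 6
    z_threshold: float = 1.96
    overlap_merge: float = 0.5
    scan_p: float = 1e-4
    min_support: int = 1
    markov_order: int = 3
    pseudocount: float = 0.01
    #: one-sided z threshold for the pair-edge co-occurrence filter
    #: (None keeps every co-occurring pair, count >= 1)
    edge_z: float | None = 1.96
    seed: int = 0
    output_dir: str | None = None

    def __post_init__(self) -> None:
        if self.k < 4:
            raise ValueError("k must be >= 4")
        for name in ("z_threshold", "overlap_merge", "scan_p"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def run_pipeline(
    dataset: seq_io.PairedDataset, config: PipelineConfig
) -> tuple[list[motif_assembly.MotifPair], dict]:
    """Run the full motif-pair discovery pipeline on a paired dataset.

    Returns the validated motif pairs and a run report with stage counts.
    Deterministic for a fixed dataset, config and seed. Intermediate
    artifacts (catalog/edge/community TSVs, PWMs, report) are written to
    ``config.output_dir`` when set.
    """
    t0 = time.time()
    report: dict = {"config": asdict(config), "stages": {}}
    out = Path(config.output_dir) if config.output_dir else None
    if out:
        out.mkdir(parents=True, exist_ok=True)

    log.info("stage background: order-%d Markov model", config.markov_order)
    background = seq_io.generate_background(
        dataset, order=config.markov_order, seed=config.seed
    )
    report["stages"]["n_pairs"] = len(dataset)

    catalogs: dict[str, kmer_stats.KmerCatalog] = {}
    cores: dict[str, set] = {}
    for side in ("A", "B"):
        cat = kmer_stats.enumerate_kmers(dataset, side, config.k)
        if not cat.records:
            raise PipelineError("enumerate_kmers", f"side {side}: no k-mers")
        bg_cat = kmer_stats.enumerate_kmers(background, side, config.k)
        sig = kmer_stats.select_significant(cat)
        if not sig.records:
            raise PipelineError("select_significant", f"side {side}: none significant")
        kmer_stats.attach_background(sig, bg_cat)
        core = kmer_stats.core_kmers(sig, config.z_threshold)
        if not core:
            raise PipelineError("core_kmers", f"side {side}: no core k-mers")
        catalogs[side] = sig
        cores[side] = core
        report["stages"][f"n_kmers_{side}"] = len(cat)
        report["stages"][f"n_significant_{side}"] = len(sig)
        report["stages"][f"n_core_{side}"] = len(core)
        if out:
            kmer_stats.write_catalog_tsv(sig, out / f"kmers_{side}.tsv")

    try:
        graph = hetero_graph.build_pair_edges(
            catalogs["A"], catalogs["B"], len(dataset), config.edge_z
        )
        raw_edges = dict(graph.pair_edges)
        graph = hetero_graph.build_neighbor_edges(graph)
        raw_edges.update(graph.neighbor_edges)
        graph = hetero_graph.normalize_weights(graph)
    except hetero_graph.GraphError as exc:
        raise PipelineError("hetero_graph", str(exc)) from exc
    report["stages"]["n_pair_edges"] = len(graph.pair_edges)
    report["stages"]["n_neighbor_edges"] = len(graph.neighbor_edges)
    if out:
        hetero_graph.write_edge_tsv(graph, raw_edges, out / "edges.tsv")

    communities = community_detect.detect_communities(
        graph, cores["A"], cores["B"]
    )
    if not communities:
        raise PipelineError("detect_communities", "no communities found")
    report["stages"]["n_communities"] = len(communities)
    merged = community_detect.merge_overlapping(
        communities, graph, config.overlap_merge
    )
    report["stages"]["n_communities_merged"] = len(merged)
    if out:
        _write_communities(merged, catalogs, out)

    motif_pairs = motif_assembly.call_motif_pairs(
        merged,
        dataset,
        catalogs["A"],
        catalogs["B"],
        p_threshold=config.scan_p,
        min_support=config.min_support,
        pseudocount=config.pseudocount,
    )
    report["stages"]["n_motif_pairs"] = len(motif_pairs)
    report["wall_time_s"] = round(time.time() - t0, 3)
    log.info(
        "pipeline done: %d motif pairs in %.1fs",
        len(motif_pairs),
        report["wall_time_s"],
    )
    if out:
        pwms = [p for mp in motif_pairs for p in (mp.pwm_a, mp.pwm_b)]
        motif_assembly.write_meme(pwms, out / "motif_pairs.meme")
        with open(out / "motif_pairs.json", "w") as fh:
            json.dump(
                [
                    {
                        "community_id": mp.community_id,
                        "pwm_a": mp.pwm_a.name,
                        "pwm_b": mp.pwm_b.name,
                        "consensus_a": mp.pwm_a.consensus,
                        "consensus_b": mp.pwm_b.consensus,
                        "n_support": mp.n_support,
                        "support": sorted(mp.support),
                    }
                    for mp in motif_pairs
                ],
                fh,
                indent=1,
            )
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=1)
    return motif_pairs, report


def _write_communities(communities, catalogs, out: Path) -> None:
    with open(out / "communities.tsv", "w") as fh:
        fh.write("community_id\tkmer\tside\tz\n")
        for cid, comm in enumerate(communities):
            for km, side in sorted(comm.nodes):
                rec = catalogs[side].records.get(km)
                z = rec.z if rec is not None else float("nan")
                fh.write(f"{cid}\t{km}\t{side}\t{z:.4g}\n")
    with open(out / "communities.json", "w") as fh:
        json.dump(
            [
                {
                    "community_id": cid,
                    "fitness": comm.fitness,
                    "n_nodes": len(comm),
                    "seed_edge": [list(n) for n in comm.seed_edge]
                    if comm.seed_edge
                    else None,
                }
                for cid, comm in enumerate(communities)
            ],
            fh,
            indent=1,
        )
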