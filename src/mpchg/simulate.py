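"""Synthetic paired-sequence datasets with implanted motif-pair consensus.

The generator emulates the benchmarking protocol the method is tested
under: sequence-pair lengths are Gaussian (mean 500 nt, sd 20 nt by
default), backgrounds are i.i.d. uniform over ACGT, and each pair
independently receives (with probability `plant_prob`) one randomly
chosen motif pair whose two CONSENSUS strings (per-column argmax base)
replace substrings at uniform random offsets. The implanted profiles and
positions are recorded as ground truth for MPD/MPFR evaluation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from mpchg.motif_assembly import PWM, read_meme, write_meme
from mpchg.seq_io import PairedDataset, SequencePair, write_paired_fasta

BASES = "ACGT"


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic dataset."""

    n_pairs: int = 300
    n_profiles: int = 10
    n_motif_pairs: int = 5
    len_mean: float = 500.0
    len_sd: float = 20.0
    plant_prob: float = 0.8
    width_range: tuple[int, int] = (8, 12)
    info: float = 0.9
    seed: int = 0
    profile_source: str = "random"  # or a MEME-format file path

    def __post_init__(self) -> None:
        if self.n_pairs < 1 or self.n_motif_pairs < 1 or self.n_profiles < 2:
            raise ValueError("invalid simulation sizes")
        if not (self.len_mean > self.len_sd > 0):
            raise ValueError("require len_mean > len_sd > 0")
        if not (0.0 <= self.plant_prob <= 1.0):
            raise ValueError("plant_prob must be in [0, 1]")


@dataclass
class GroundTruth:
    """Planted motif pairs and per-pair implant positions."""

    motif_pairs: list[tuple[PWM, PWM]]
    implants: dict[str, tuple[int, int, int]] = field(default_factory=dict)
    # pair_id -> (motif-pair index, offset_a, offset_b)


def random_profiles(
    h: int,
    width_range: tuple[int, int] = (8, 12),
    info: float = 0.9,
    seed: int = 0,
) -> list[PWM]:
    """Seeded random profiles: one dominant base per column.

    The dominant base carries probability `info`; the remaining mass is
    uniform over the other three bases.
    """
    if h < 1:
        raise ValueError("need at least one profile")
    if not (0.25 < info <= 1.0):
        raise ValueError("info must be in (0.25, 1]")
    rng = np.random.default_rng(seed)
    lo, hi = width_range
    profiles = []
    for i in range(h):
        width = int(rng.integers(lo, hi + 1))
        dominant = rng.integers(0, 4, size=width)
        mat = np.full((width, 4), (1.0 - info) / 3.0)
        mat[np.arange(width), dominant] = info
        profiles.append(PWM(matrix=mat, name=f"profile{i}"))
    return profiles


def _combine_pairs(
    n_profiles: int, n_motif_pairs: int, rng: np.random.Generator
) -> list[tuple[int, int]]:
    """Random profile combinations forming the planted motif pairs.

    While enough profiles are available, each profile is used at most
    once (a random perfect matching), so every known pair is unambiguous
    in the ground truth; beyond that, distinct profile pairs are drawn
    with reuse.
    """
    if 2 * n_motif_pairs <= n_profiles:
        perm = rng.permutation(n_profiles)
        return [
            (int(perm[2 * i]), int(perm[2 * i + 1])) for i in range(n_motif_pairs)
        ]
    all_pairs = [
        (i, j) for i in range(n_profiles) for j in range(n_profiles) if i != j
    ]
    if n_motif_pairs > len(all_pairs):
        raise ValueError("more motif pairs requested than distinct profile pairs")
    idx = rng.choice(len(all_pairs), size=n_motif_pairs, replace=False)
    return [all_pairs[i] for i in idx]


def simulate_dataset(config: SimulationConfig) -> tuple[PairedDataset, GroundTruth]:
    """Generate one synthetic dataset plus its ground truth (fully seeded)."""
    rng = np.random.default_rng(config.seed)
    if config.profile_source == "random":
        profiles = random_profiles(
            config.n_profiles, config.width_range, config.info, seed=int(rng.integers(2**31))
        )
    else:
        profiles = list(read_meme(config.profile_source).values())
        if len(profiles) < config.n_profiles:
            raise ValueError(
                f"profile file has {len(profiles)} motifs, need {config.n_profiles}"
            )
        keep = rng.choice(len(profiles), size=config.n_profiles, replace=False)
        profiles = [profiles[i] for i in keep]
    combos = _combine_pairs(config.n_profiles, config.n_motif_pairs, rng)
    motif_pairs = [(profiles[i], profiles[j]) for i, j in combos]
    consensus = [(pa.consensus, pb.consensus) for pa, pb in motif_pairs]
    max_width = max(max(len(ca), len(cb)) for ca, cb in consensus)
    min_len = 2 * max_width

    n = config.n_pairs
    lengths_a = np.maximum(
        np.rint(rng.normal(config.len_mean, config.len_sd, size=n)).astype(int),
        min_len,
    )
    lengths_b = np.maximum(
        np.rint(rng.normal(config.len_mean, config.len_sd, size=n)).astype(int),
        min_len,
    )
    if config.len_mean < min_len:
        raise ValueError("motifs wider than half the mean sequence length")

    truth = GroundTruth(motif_pairs=motif_pairs)
    pairs = []
    width_id = len(str(n))
    for i in range(n):
        pid = f"sim{i:0{width_id}d}"
        seq_a = rng.integers(0, 4, size=lengths_a[i])
        seq_b = rng.integers(0, 4, size=lengths_b[i])
        sa = "".join(BASES[c] for c in seq_a)
        sb = "".join(BASES[c] for c in seq_b)
        if rng.random() < config.plant_prob:
            m_idx = int(rng.integers(len(motif_pairs)))
            ca, cb = consensus[m_idx]
            off_a = int(rng.integers(0, lengths_a[i] - len(ca) + 1))
            off_b = int(rng.integers(0, lengths_b[i] - len(cb) + 1))
            sa = sa[:off_a] + ca + sa[off_a + len(ca) :]
            sb = sb[:off_b] + cb + sb[off_b + len(cb) :]
            truth.implants[pid] = (m_idx, off_a, off_b)
        pairs.append(SequencePair(pid, sa, sb))
    return PairedDataset(pairs), truth


def write_simulation(
    dataset: PairedDataset, truth: GroundTruth, out_dir: str | Path
) -> None:
    """Write the FASTA pair, ground-truth JSON, and planted PWMs (MEME)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_paired_fasta(dataset, out / "side_a.fa", out / "side_b.fa")
    pwms = []
    for i, (pa, pb) in enumerate(truth.motif_pairs):
        pa.name = f"pair{i}_A"
        pb.name = f"pair{i}_B"
        pwms.extend([pa, pb])
    write_meme(pwms, out / "planted_motifs.meme")
    payload = {
        "motif_pairs": [
            {"index": i, "pwm_a": pa.name, "pwm_b": pb.name,
             "consensus_a": pa.consensus, "consensus_b": pb.consensus}
            for i, (pa, pb) in enumerate(truth.motif_pairs)
        ],
        "implants": {
            pid: {"motif_pair": mi, "offset_a": oa, "offset_b": ob}
            for pid, (mi, oa, ob) in truth.implants.items()
        },
    }
    with open(out / "ground_truth.json", "w") as fh:
        json.dump(payload, fh, indent=1)


def load_truth_motifs(out_dir: str | Path) -> list[tuple[PWM, PWM]]:
    """Reload planted motif pairs written by :func:`write_simulation`."""
    out = Path(out_dir)
    pwms = read_meme(out / "planted_motifs.meme")
    with open(out / "ground_truth.json") as fh:
        payload = json.load(fh)
    return [
        (pwms[mp["pwm_a"]], pwms[mp["pwm_b"]])
        for mp in payload["motif_pairs"]
    ]
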