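"""Paired sequence I/O and Markov background generation.

A dataset is two index-aligned FASTA files: the i-th record of file A and
the i-th record of file B form one sequence pair (side A = "enhancer",
side B = "promoter" by convention; the labels are free text).

Background sequences are sampled from a third-order Markov model trained
per side, so each background sequence matches its real counterpart in
length while the corpus matches the side's local nucleotide composition.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

VALID_BASES = frozenset("ACGTN")
BASES = "ACGT"


class InputError(ValueError):
    """Raised when the paired input violates a precondition."""


@dataclass(frozen=True)
class SequencePair:
    """One paired record: side-A sequence, side-B sequence, shared id."""

    pair_id: str
    seq_a: str
    seq_b: str

    def __post_init__(self) -> None:
        for seq in (self.seq_a, self.seq_b):
            bad = set(seq) - VALID_BASES
            if bad:
                raise InputError(
                    f"pair {self.pair_id!r}: invalid characters {sorted(bad)}"
                )


@dataclass
class PairedDataset:
    """Ordered collection of sequence pairs with per-side labels."""

    pairs: list[SequencePair]
    side_a_label: str = "enhancer"
    side_b_label: str = "promoter"

    def __post_init__(self) -> None:
        if not self.pairs:
            raise InputError("dataset must contain at least one sequence pair")
        ids = [p.pair_id for p in self.pairs]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise InputError(f"duplicate pair_id(s): {dup[:5]}")

    def __len__(self) -> int:
        return len(self.pairs)

    def __iter__(self) -> Iterator[SequencePair]:
        return iter(self.pairs)

    def sequences(self, side: str) -> list[str]:
        """All sequences of one side ('A' or 'B'), in pair order."""
        if side == "A":
            return [p.seq_a for p in self.pairs]
        if side == "B":
            return [p.seq_b for p in self.pairs]
        raise ValueError(f"side must be 'A' or 'B', got {side!r}")


def read_paired_fasta(path_a: str | Path, path_b: str | Path) -> PairedDataset:
    """Read two index-aligned FASTA files into a :class:`PairedDataset`.

    The i-th records of the two files form the i-th pair; the pair id is
    the record id of file A. Sequences are uppercased.
    """
    recs_a = list(SeqIO.parse(str(path_a), "fasta"))
    recs_b = list(SeqIO.parse(str(path_b), "fasta"))
    if not recs_a or not recs_b:
        raise InputError(f"empty FASTA input: {path_a if not recs_a else path_b}")
    if len(recs_a) != len(recs_b):
        raise InputError(
            f"record counts differ between {path_a} and {path_b}: "
            f"{len(recs_a)} vs {len(recs_b)}"
        )
    pairs = [
        SequencePair(ra.id, str(ra.seq).upper(), str(rb.seq).upper())
        for ra, rb in zip(recs_a, recs_b)
    ]
    return PairedDataset(pairs)


def write_paired_fasta(
    dataset: PairedDataset, path_a: str | Path, path_b: str | Path
) -> None:
    """Write the two sides as FASTA (80-column wrapped)."""
    recs_a = [
        SeqRecord(Seq(p.seq_a), id=p.pair_id, description="") for p in dataset
    ]
    recs_b = [
        SeqRecord(Seq(p.seq_b), id=p.pair_id, description="") for p in dataset
    ]
    SeqIO.write(recs_a, str(path_a), "fasta")
    SeqIO.write(recs_b, str(path_b), "fasta")


def _encode(seq: str) -> np.ndarray:
    """Map a DNA string to integer codes A=0 C=1 G=2 T=3, N (or other)=4."""
    table = np.full(256, 4, dtype=np.int64)
    for i, b in enumerate(BASES):
        table[ord(b)] = i
    return table[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


@dataclass
class MarkovModel:
    """Fixed-order Markov chain over ACGT with add-one smoothing.

    Transition probabilities condition on the previous `order` bases;
    training windows containing N contribute nothing. The initial context
    of a generated sequence is drawn from the empirical context
    distribution, so even short outputs are composition-matched. Contexts
    never observed in training fall back to the 0-order base frequencies.
    """

    order: int
    trans_cum: np.ndarray  # (4**order, 4) cumulative transition probs
    context_codes: np.ndarray  # observed contexts, integer-coded
    context_probs: np.ndarray
    base_probs: np.ndarray

    @classmethod
    def fit(cls, sequences: Sequence[str], order: int) -> "MarkovModel":
        if order < 0:
            raise ValueError("order must be >= 0")
        n_ctx = 4**order
        counts = np.zeros((n_ctx, 4), dtype=np.float64)
        base_counts = np.zeros(4, dtype=np.float64)
        weights = 4 ** np.arange(order - 1, -1, -1) if order else np.zeros(0)
        for seq in sequences:
            codes = _encode(seq)
            base_counts += np.bincount(codes[codes < 4], minlength=4)
            if len(codes) < order + 1:
                continue
            # context code at i covers codes[i : i + order]
            if order:
                valid = codes < 4
                win_ok = (
                    np.lib.stride_tricks.sliding_window_view(valid, order + 1)
                    .all(axis=1)
                )
                ctx = np.lib.stride_tricks.sliding_window_view(
                    np.where(valid, codes, 0), order
                )[:-1] @ weights
                nxt = codes[order:]
                np.add.at(counts, (ctx[win_ok], nxt[win_ok]), 1.0)
            else:
                ok = codes < 4
                np.add.at(counts, (np.zeros(ok.sum(), int), codes[ok]), 1.0)
        if base_counts.sum() == 0:
            raise InputError("cannot train Markov model: no A/C/G/T bases")
        base_probs = base_counts / base_counts.sum()
        ctx_totals = counts.sum(axis=1)
        observed = ctx_totals > 0
        probs = np.tile(base_probs, (n_ctx, 1))
        # add-one smoothing on observed transition counts
        smoothed = (counts[observed] + 1.0) / (ctx_totals[observed] + 4.0)[:, None]
        probs[observed] = smoothed
        context_codes = np.flatnonzero(observed)
        context_probs = (
            ctx_totals[observed] / ctx_totals.sum()
            if observed.any()
            else np.ones(0)
        )
        return cls(
            order=order,
            trans_cum=np.cumsum(probs, axis=1),
            context_codes=context_codes,
            context_probs=context_probs,
            base_probs=base_probs,
        )

    def transition_probs(self, context: str) -> np.ndarray:
        """Smoothed P(next base | context) for a given context string."""
        if len(context) != self.order:
            raise ValueError(f"context must have length {self.order}")
        code = int(_encode(context) @ (4 ** np.arange(self.order - 1, -1, -1)))
        cum = self.trans_cum[code]
        return np.diff(cum, prepend=0.0)

    def sample(self, length: int, rng: np.random.Generator) -> str:
        """Generate one sequence of exactly `length` bases (never N)."""
        if length <= 0:
            return ""
        if self.order == 0 or len(self.context_codes) == 0:
            idx = rng.choice(4, size=length, p=self.base_probs)
            return "".join(BASES[i] for i in idx)
        ctx = int(
            self.context_codes[rng.choice(len(self.context_codes), p=self.context_probs)]
        )
        # decode the initial context into bases (most significant first)
        ctx_bases = []
        c = ctx
        for _ in range(self.order):
            ctx_bases.append(BASES[c % 4])
            c //= 4
        out = list(reversed(ctx_bases))[:length]
        if len(out) >= length:
            return "".join(out[:length])
        us = rng.random(length - len(out))
        mod = 4 ** (self.order - 1)
        cum = self.trans_cum
        for u in us:
            row = cum[ctx]
            b = 0 if u < row[0] else 1 if u < row[1] else 2 if u < row[2] else 3
            out.append(BASES[b])
            ctx = (ctx % mod) * 4 + b
        return "".join(out)


def generate_background(
    dataset: PairedDataset, order: int = 3, seed: int = 0
) -> PairedDataset:
    """Sample a background dataset matched in pair count and lengths.

    One Markov model per side, trained on all real sequences of that side;
    the two sides typically differ in base composition (promoters are
    GC-rich), so they are never pooled.
    """
    rng = np.random.default_rng(seed)
    model_a = MarkovModel.fit(dataset.sequences("A"), order)
    model_b = MarkovModel.fit(dataset.sequences("B"), order)
    pairs = [
        SequencePair(
            p.pair_id,
            model_a.sample(len(p.seq_a), rng),
            model_b.sample(len(p.seq_b), rng),
        )
        for p in dataset
    ]
    return PairedDataset(
        pairs, dataset.side_a_label + "_bg", dataset.side_b_label + "_bg"
    )
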