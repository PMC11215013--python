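"""PWM assembly from communities and log-odds scanning of sequence pairs.

Each community is split by side; the endpoints of its heaviest internal
pair edge become the two center k-mers. Same-side k-mers are aligned to
their center by mismatch (offset 0) or best suffix-prefix overlap, each
contributing its sequence frequency to the base counts of the columns it
covers. The resulting PWM pair is validated by scanning the real
sequences with an exact-null log-odds scanner: the p-value of a score is
computed from the full score distribution under a 0-order background
model, obtained by dynamic programming over columns.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import numpy as np

from mpchg.community_detect import Community
from mpchg.hetero_graph import overlap_shifts
from mpchg.kmer_stats import KmerCatalog, revcomp
from mpchg.seq_io import PairedDataset, _encode

log = logging.getLogger(__name__)

BASES = "ACGT"
_SCALE = 1000  # log-odds discretization: integer units of 1/_SCALE bits


@dataclass
class PWM:
    """Column-stochastic position weight matrix over ACGT."""

    matrix: np.ndarray  # (L, 4) probabilities, rows sum to 1
    counts: np.ndarray | None = None  # pre-normalization weighted counts
    source_kmers: dict[str, int] = field(default_factory=dict)  # kmer -> offset
    side: str | None = None
    name: str = "motif"

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4:
            raise ValueError("PWM matrix must have shape (L, 4)")
        if self.matrix.shape[0] < 4:
            raise ValueError("PWM must span at least 4 columns")
        if not np.allclose(self.matrix.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("PWM columns must sum to 1")

    def __len__(self) -> int:
        return self.matrix.shape[0]

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.matrix.argmax(axis=1))

    def reverse_complement(self) -> "PWM":
        return PWM(
            matrix=self.matrix[::-1, ::-1].copy(),
            source_kmers=dict(self.source_kmers),
            side=self.side,
            name=self.name + "_rc",
        )


@dataclass
class ScanHit:
    pair_id: str
    side: str
    offset: int
    strand: str
    score: float
    p_value: float


@dataclass
class MotifPair:
    """Two PWMs (one per side) supported by co-occurring scan hits."""

    pwm_a: PWM
    pwm_b: PWM
    community_id: int
    support: set[str] = field(default_factory=set)

    @property
    def n_support(self) -> int:
        return len(self.support)


def split_and_center(
    community: Community,
) -> tuple[tuple[set[str], str], tuple[set[str], str]] | None:
    """Partition a community by side; centers = heaviest pair edge.

    Returns ((kmers_A, center_A), (kmers_B, center_B)), or None when one
    side is empty (the community is then skipped).
    """
    kmers_a = {km for km, side in community.nodes if side == "A"}
    kmers_b = {km for km, side in community.nodes if side == "B"}
    if not kmers_a or not kmers_b or not community.pair_weights:
        log.warning("community skipped: one side has no k-mers")
        return None
    # max weight; ties -> lexicographically smaller (kmer_a, kmer_b)
    best = max(
        community.pair_weights.items(),
        key=lambda item: (
            item[1],
            tuple(-ord(c) for c in item[0][0][0] + item[0][1][0]),
        ),
    )
    ((center_a, _), (center_b, _)) = best[0]
    return (kmers_a, center_a), (kmers_b, center_b)


def _best_relation(anchor: str, kmer: str) -> tuple[int, int] | None:
    """Relative placement of `kmer` against `anchor`.

    Returns (shift, quality) or None; mismatch-1 gives shift 0 with top
    quality, otherwise the longest >= 4-base suffix-prefix overlap wins,
    ties resolved toward the smaller |shift| (then positive shift).
    """
    k = len(anchor)
    if anchor != kmer and sum(a != b for a, b in zip(anchor, kmer)) == 1:
        return 0, k  # one mismatch: full-length alignment
    shifts = overlap_shifts(anchor, kmer)
    if not shifts:
        return None
    shifts.sort(key=lambda sv: (-sv[1], abs(sv[0]), -sv[0]))
    shift, ov = shifts[0]
    return shift, ov


@dataclass(frozen=True)
class Placement:
    """Where one k-mer sits relative to the center (column 0)."""

    offset: int
    oriented: str  # the strand of the k-mer actually aligned
    strand: str  # '+' if the canonical string itself, '-' if its revcomp


def align_to_center(kmers: set[str], center: str) -> dict[str, Placement]:
    """Place each k-mer relative to the center (center at offset 0).

    Canonicalization collapsed strands, so a k-mer may relate to the
    center only through its reverse complement; the forward (canonical)
    orientation is preferred and the reverse complement is tried when the
    forward string has no mismatch/overlap relation to any placed k-mer.
    K-mers unrelated to the center are placed through already-placed
    k-mers when a relation exists (transitive chaining); the rest are
    dropped.
    """
    placed: dict[str, Placement] = {center: Placement(0, center, "+")}
    pending = set(kmers) - {center}
    progress = True
    while progress and pending:
        progress = False
        best: dict[str, tuple[tuple, Placement]] = {}
        for km in pending:
            for variant, strand in ((km, "+"), (revcomp(km), "-")):
                found_any = False
                for anchor in placed.values():
                    rel = _best_relation(anchor.oriented, variant)
                    if rel is None:
                        continue
                    found_any = True
                    shift, quality = rel
                    off = anchor.offset + shift
                    # prefer forward orientation, then relation quality,
                    # then the placement closest to the center
                    rank = (strand == "+", quality, -abs(off), off)
                    cur = best.get(km)
                    if cur is None or rank > cur[0]:
                        best[km] = (rank, Placement(off, variant, strand))
                if strand == "+" and found_any:
                    break  # forward relation exists; never use revcomp
        for km, (_, placement) in best.items():
            placed[km] = placement
            pending.discard(km)
            progress = True
    if pending:
        log.debug("dropped %d k-mers unrelated to center %s", len(pending), center)
    return placed


def build_pwm(
    aligned: dict[str, Placement],
    catalog: KmerCatalog,
    pseudocount: float = 0.01,
    center: str | None = None,
    side: str | None = None,
    name: str = "motif",
    min_flank_coverage: int = 1,
) -> PWM:
    """Weighted base counts over the aligned span, trimmed and normalized.

    Each k-mer (in its aligned orientation) adds its sequence frequency
    to the count of its base at every column it covers. Flanking columns
    covered by fewer than `min_flank_coverage` source k-mers are
    trimmed, except columns inside the center's own span; the default of
    1 keeps the full aligned span, since the terminal columns of a
    cleanly tiled motif are covered by a single window by construction.
    A relative pseudocount (total mass `pseudocount`, uniform over
    bases) keeps every probability positive.
    """
    if not aligned:
        raise ValueError("cannot build a PWM from an empty alignment")
    k = len(next(iter(aligned)))
    if center is None:
        center = min(aligned, key=lambda km: (abs(aligned[km].offset), km))
    lo = min(p.offset for p in aligned.values())
    hi = max(p.offset for p in aligned.values()) + k
    length = hi - lo
    counts = np.zeros((length, 4))
    coverage = np.zeros(length, dtype=int)
    base_idx = {b: i for i, b in enumerate(BASES)}
    for km, placement in aligned.items():
        rec = catalog.records.get(km)
        weight = rec.p_real if rec is not None else 1.0
        for j, base in enumerate(placement.oriented):
            col = placement.offset - lo + j
            counts[col, base_idx[base]] += weight
            coverage[col] += 1
    # trim undersupported flanks, but never inside the center's span
    c_lo = aligned[center].offset - lo
    c_hi = c_lo + k
    start, stop = 0, length
    while start < c_lo and coverage[start] < min_flank_coverage:
        start += 1
    while stop > c_hi and coverage[stop - 1] < min_flank_coverage:
        stop -= 1
    counts = counts[start:stop]
    if counts.shape[0] < 4:
        counts = np.zeros((k, 4))
        rec = catalog.records.get(center)
        weight = rec.p_real if rec is not None else 1.0
        for j, base in enumerate(center):
            counts[j, base_idx[base]] += weight
        aligned = {center: Placement(0, center, "+")}
    col_tot = counts.sum(axis=1, keepdims=True)
    probs = counts / col_tot
    matrix = (probs + pseudocount / 4.0) / (1.0 + pseudocount)
    return PWM(
        matrix=matrix,
        counts=counts,
        source_kmers={km: p.offset for km, p in aligned.items()},
        side=side,
        name=name,
    )


def _background_freqs(dataset: PairedDataset, side: str) -> np.ndarray:
    counts = np.zeros(4)
    for seq in dataset.sequences(side):
        codes = _encode(seq)
        counts += np.bincount(codes[codes < 4], minlength=4)
    if counts.sum() == 0:
        raise ValueError("no A/C/G/T bases on scanned side")
    return counts / counts.sum()


class PwmScanner:
    """Exact-null log-odds scanner for one PWM and background.

    Scores are log2(p_col / bg) summed over columns, discretized to
    integer units of 1/1000 bit. The null distribution of the integer
    score under the i.i.d. background model is computed by dynamic
    programming over columns; the p-value of a hit is the probability of
    an equal or greater score.
    """

    def __init__(self, pwm: PWM, background: np.ndarray):
        self.pwm = pwm
        self.background = np.asarray(background, dtype=float)
        if self.background.shape != (4,) or not np.isclose(self.background.sum(), 1):
            raise ValueError("background must be 4 probabilities summing to 1")
        logodds = np.log2(pwm.matrix / self.background[None, :])
        self.int_scores = np.rint(logodds * _SCALE).astype(np.int64)  # (L, 4)
        self._pvals, self._min_score = self._null_distribution()

    def _null_distribution(self) -> tuple[np.ndarray, int]:
        lo = int(self.int_scores.min(axis=1).sum())
        hi = int(self.int_scores.max(axis=1).sum())
        pmf = np.zeros(hi - lo + 1)
        # DP over columns; index = score - running minimum
        pmf[0] = 1.0
        cur_lo, cur_len = 0, 1
        for col in range(self.int_scores.shape[0]):
            col_scores = self.int_scores[col]
            col_lo = int(col_scores.min())
            new_lo = cur_lo + col_lo
            new_len = cur_len + int(col_scores.max()) - col_lo
            new = np.zeros(new_len)
            for b in range(4):
                shift = int(col_scores[b]) - col_lo
                new[shift : shift + cur_len] += pmf[:cur_len] * self.background[b]
            pmf = new
            cur_lo, cur_len = new_lo, new_len
        # survival function: P(score >= s)
        sf = np.cumsum(pmf[::-1])[::-1]
        return sf, cur_lo

    def p_value(self, int_score: int) -> float:
        idx = int_score - self._min_score
        if idx < 0:
            return 1.0
        if idx >= len(self._pvals):
            return float(self._pvals[-1])
        return float(self._pvals[idx])

    def score_sequence(self, codes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Integer scores at every valid offset; invalid offsets masked.

        Returns (scores, valid) arrays of length len(codes) - L + 1.
        """
        L = len(self.pwm)
        if len(codes) < L:
            return np.zeros(0, dtype=np.int64), np.zeros(0, dtype=bool)
        valid_base = codes < 4
        windows_ok = np.lib.stride_tricks.sliding_window_view(valid_base, L).all(axis=1)
        safe = np.where(valid_base, codes, 0)
        win = np.lib.stride_tricks.sliding_window_view(safe, L)  # (n, L)
        scores = np.zeros(win.shape[0], dtype=np.int64)
        for col in range(L):
            scores += self.int_scores[col][win[:, col]]
        return scores, windows_ok


def scan(
    pwm: PWM,
    dataset: PairedDataset,
    side: str,
    p_threshold: float = 1e-4,
    background: np.ndarray | None = None,
) -> list[ScanHit]:
    """Scan one side of every sequence pair on both strands.

    A position is a hit when the exact-null p-value of its log-odds
    score is strictly below `p_threshold`. Windows containing N are
    skipped. Minus-strand hits are reported at the window's offset on
    the given (forward) sequence.
    """
    if background is None:
        background = _background_freqs(dataset, side)
    fwd = PwmScanner(pwm, background)
    rev = PwmScanner(pwm.reverse_complement(), background)
    hits: list[ScanHit] = []
    L = len(pwm)
    any_long_enough = False
    for pair in dataset:
        seq = pair.seq_a if side == "A" else pair.seq_b
        if len(seq) < L:
            continue
        any_long_enough = True
        codes = _encode(seq)
        for scanner, strand in ((fwd, "+"), (rev, "-")):
            scores, ok = scanner.score_sequence(codes)
            for off in np.flatnonzero(ok):
                p = scanner.p_value(int(scores[off]))
                if p < p_threshold:
                    hits.append(
                        ScanHit(
                            pair.pair_id,
                            side,
                            int(off),
                            strand,
                            scores[off] / _SCALE,
                            p,
                        )
                    )
    if not any_long_enough:
        log.warning("PWM (L=%d) longer than every scanned sequence", L)
    return hits


def community_to_pwm_pair(
    community: Community,
    catalog_a: KmerCatalog,
    catalog_b: KmerCatalog,
    pseudocount: float = 0.01,
    name: str = "motif",
) -> tuple[PWM, PWM] | None:
    """Assemble the two side PWMs of one community (None if one-sided)."""
    split = split_and_center(community)
    if split is None:
        return None
    (kmers_a, center_a), (kmers_b, center_b) = split
    aligned_a = align_to_center(kmers_a, center_a)
    aligned_b = align_to_center(kmers_b, center_b)
    pwm_a = build_pwm(
        aligned_a, catalog_a, pseudocount, center=center_a, side="A", name=name + "_A"
    )
    pwm_b = build_pwm(
        aligned_b, catalog_b, pseudocount, center=center_b, side="B", name=name + "_B"
    )
    return pwm_a, pwm_b


def call_motif_pairs(
    communities: list[Community],
    dataset: PairedDataset,
    catalog_a: KmerCatalog,
    catalog_b: KmerCatalog,
    p_threshold: float = 1e-4,
    min_support: int = 1,
    pseudocount: float = 0.01,
) -> list[MotifPair]:
    """Validate each community's PWM pair by scanning the real pairs.

    A sequence pair supports a motif pair when the A-side PWM hits its
    A sequence and the B-side PWM hits its B sequence. Pairs with
    support below `min_support` are dropped; the rest are sorted by
    support (descending).
    """
    bg_a = _background_freqs(dataset, "A")
    bg_b = _background_freqs(dataset, "B")
    out: list[MotifPair] = []
    for idx, comm in enumerate(communities):
        pwms = community_to_pwm_pair(
            comm, catalog_a, catalog_b, pseudocount, name=f"pair{idx}"
        )
        if pwms is None:
            continue
        pwm_a, pwm_b = pwms
        hits_a = scan(pwm_a, dataset, "A", p_threshold, background=bg_a)
        hits_b = scan(pwm_b, dataset, "B", p_threshold, background=bg_b)
        support = {h.pair_id for h in hits_a} & {h.pair_id for h in hits_b}
        if len(support) >= min_support:
            out.append(MotifPair(pwm_a, pwm_b, idx, support))
        else:
            log.info("motif pair %d dropped: support %d", idx, len(support))
    out.sort(key=lambda mp: (-mp.n_support, mp.community_id))
    return out


def write_meme(pwms: list[PWM], path, background: np.ndarray | None = None) -> None:
    """Write PWMs in MEME minimal motif format."""
    bg = background if background is not None else np.full(4, 0.25)
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
        fh.write("Background letter frequencies\n")
        fh.write(" ".join(f"{b} {p:.4f}" for b, p in zip(BASES, bg)) + "\n\n")
        for pwm in pwms:
            nsites = max(len(pwm.source_kmers), 1)
            fh.write(f"MOTIF {pwm.name}\n")
            fh.write(
                f"letter-probability matrix: alength= 4 w= {len(pwm)} "
                f"nsites= {nsites} E= 0\n"
            )
            for row in pwm.matrix:
                fh.write(" " + " ".join(f"{p:.6f}" for p in row) + "\n")
            fh.write("\n")


def read_meme(path) -> dict[str, PWM]:
    """Read a MEME minimal motif file into {motif_id: PWM}."""
    pwms: dict[str, PWM] = {}
    name = None
    rows: list[list[float]] = []
    expect = 0
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith("MOTIF"):
                name = line.split()[1]
                rows, expect = [], 0
            elif line.startswith("letter-probability matrix"):
                m = re.search(r"w=\s*(\d+)", line)
                if m is None:
                    raise ValueError(f"malformed matrix header in {path}: {line!r}")
                expect = int(m.group(1))
            elif name is not None and expect and line and line[0] in "0123456789.":
                rows.append([float(x) for x in line.split()])
                if len(rows) == expect:
                    mat = np.array(rows)
                    mat = mat / mat.sum(axis=1, keepdims=True)
                    pwms[name] = PWM(matrix=mat, name=name)
                    name, expect, rows = None, 0, []
    return pwms
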