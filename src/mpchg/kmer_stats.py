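"""Canonical k-mer enumeration, significance selection and z-scoring.

k-mers are collapsed with their reverse complements (canonical form =
lexicographic minimum of the two), low-complexity k-mers are excluded,
"significant" k-mers are those whose frequency exceeds the side's mean by
more than one standard deviation, and "core" k-mers additionally show
enrichment over a matched background at a pooled two-proportion z-score
above 1.96.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from mpchg.seq_io import PairedDataset, _encode

log = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGT", "TGCA")

#: occurrence record: (0-based offset, strand) within one sequence
Occurrence = tuple[int, str]


def revcomp(kmer: str) -> str:
    return kmer.translate(_COMPLEMENT)[::-1]


def canonical(kmer: str) -> str:
    """Lexicographic minimum of a k-mer and its reverse complement."""
    if set(kmer) - set("ACGT"):
        raise ValueError(f"non-ACGT character in k-mer {kmer!r}")
    rc = revcomp(kmer)
    return kmer if kmer <= rc else rc


def is_low_complexity(kmer: str) -> bool:
    """True iff one base occupies at least k-1 of the k positions."""
    return max(kmer.count(b) for b in "ACGT") >= len(kmer) - 1


@dataclass
class KmerRecord:
    """A canonical k-mer with its counts, frequencies and occurrence map."""

    kmer: str
    side: str
    n_real: int = 0
    n_bg: int = 0
    p_real: float = 0.0
    p_bg: float = 0.0
    z: float = float("nan")
    occurrences: dict[str, set[Occurrence]] = field(default_factory=dict)

    @property
    def pair_ids(self) -> frozenset[str]:
        return frozenset(self.occurrences)


@dataclass
class KmerCatalog:
    """All retained canonical k-mers of one side, with frequency moments."""

    side: str
    k: int
    records: dict[str, KmerRecord]
    freq_mean: float = 0.0
    freq_sd: float = 0.0
    total_real: int = 0
    total_bg: int = 0

    def __len__(self) -> int:
        return len(self.records)


# Precomputed canonical/strand lookup tables per k, keyed by k.
_CANON_CACHE: dict[int, tuple[np.ndarray, np.ndarray]] = {}


def _canon_tables(k: int) -> tuple[np.ndarray, np.ndarray]:
    """(canonical_code, is_forward) lookup arrays over all 4**k codes.

    Codes read most-significant-base-first, so the code order equals the
    lexicographic order of the strings and min(code, rc_code) is the
    canonical form.
    """
    if k in _CANON_CACHE:
        return _CANON_CACHE[k]
    codes = np.arange(4**k, dtype=np.int64)
    rc = np.zeros_like(codes)
    tmp = codes.copy()
    for _ in range(k):
        rc = rc * 4 + (3 - tmp % 4)
        tmp //= 4
    canon = np.minimum(codes, rc)
    _CANON_CACHE[k] = (canon, codes <= rc)
    return _CANON_CACHE[k]


def _decode(code: int, k: int) -> str:
    out = []
    for _ in range(k):
        out.append("ACGT"[code % 4])
        code //= 4
    return "".join(reversed(out))


def enumerate_kmers(dataset: PairedDataset, side: str, k: int = 6) -> KmerCatalog:
    """Count every canonical k-mer of one side with a sliding window.

    Windows containing N are skipped. Occurrence positions are recorded as
    (offset, strand): '+' when the window itself is canonical, '-' when
    its reverse complement is. Low-complexity canonical k-mers are removed
    before frequencies are computed.
    """
    if k < 4:
        raise ValueError("k must be >= 4")
    canon_tab, fwd_tab = _canon_tables(k)
    weights = 4 ** np.arange(k - 1, -1, -1)
    records: dict[int, KmerRecord] = {}
    n_windows = 0
    for pair in dataset:
        seq = pair.seq_a if side == "A" else pair.seq_b
        if len(seq) < k:
            continue
        codes = _encode(seq)
        valid = codes < 4
        win_valid = np.lib.stride_tricks.sliding_window_view(valid, k).all(axis=1)
        win_codes = (
            np.lib.stride_tricks.sliding_window_view(np.where(valid, codes, 0), k)
            @ weights
        )
        offsets = np.flatnonzero(win_valid)
        if offsets.size == 0:
            continue
        n_windows += offsets.size
        wc = win_codes[offsets]
        canon_codes = canon_tab[wc]
        fwd = fwd_tab[wc]
        for off, cc, is_fwd in zip(offsets.tolist(), canon_codes.tolist(), fwd.tolist()):
            rec = records.get(cc)
            if rec is None:
                rec = records[cc] = KmerRecord(_decode(cc, k), side)
            rec.n_real += 1
            rec.occurrences.setdefault(pair.pair_id, set()).add(
                (off, "+" if is_fwd else "-")
            )
    if not records:
        log.warning("side %s: no k-mer windows at k=%d", side, k)
        return KmerCatalog(side, k, {})
    retained = {
        rec.kmer: rec for rec in records.values() if not is_low_complexity(rec.kmer)
    }
    total = sum(rec.n_real for rec in retained.values())
    freqs = []
    for rec in retained.values():
        rec.p_real = rec.n_real / total
        freqs.append(rec.p_real)
    arr = np.asarray(freqs)
    return KmerCatalog(
        side,
        k,
        retained,
        freq_mean=float(arr.mean()),
        freq_sd=float(arr.std()),
        total_real=total,
    )


def select_significant(catalog: KmerCatalog) -> KmerCatalog:
    """Keep k-mers with frequency strictly above mean + 1 sd.

    Frequencies are NOT renormalized after selection: they stay fractions
    of the full retained-k-mer total of the side.
    """
    if len(catalog.records) < 2:
        raise ValueError(
            "need at least 2 k-mer records to define a frequency sd"
        )
    cut = catalog.freq_mean + catalog.freq_sd
    kept = {km: rec for km, rec in catalog.records.items() if rec.p_real > cut}
    if not kept:
        log.warning("side %s: no significant k-mers", catalog.side)
    return KmerCatalog(
        catalog.side,
        catalog.k,
        kept,
        freq_mean=catalog.freq_mean,
        freq_sd=catalog.freq_sd,
        total_real=catalog.total_real,
        total_bg=catalog.total_bg,
    )


def z_score(n_real: int, n_bg: int, total_real: int, total_bg: int) -> float:
    """Pooled two-proportion z statistic for one k-mer.

    The proportions are k-mer counts over the side's total retained
    count, and the standard error uses those same global totals
    (1/total_real + 1/total_bg), implemented exactly as defined.
    """
    if total_real <= 0 or total_bg <= 0:
        raise ValueError("totals must be positive")
    p_real = n_real / total_real
    p_bg = n_bg / total_bg
    pooled = (n_real + n_bg) / (total_real + total_bg)
    if pooled <= 0.0 or pooled >= 1.0:
        return 0.0
    se = math.sqrt(pooled * (1.0 - pooled) * (1.0 / total_real + 1.0 / total_bg))
    return (p_real - p_bg) / se


def attach_background(catalog: KmerCatalog, bg_catalog: KmerCatalog) -> KmerCatalog:
    """Fill in background counts/frequencies and z-scores in place.

    The selection made on the real side is kept as-is: each selected
    k-mer's background count is looked up (0 if absent), never
    re-selected by background frequency.
    """
    total_bg = bg_catalog.total_real
    if total_bg <= 0:
        raise ValueError("background catalog is empty")
    catalog.total_bg = total_bg
    for rec in catalog.records.values():
        bg_rec = bg_catalog.records.get(rec.kmer)
        rec.n_bg = bg_rec.n_real if bg_rec is not None else 0
        rec.p_bg = rec.n_bg / total_bg
        rec.z = z_score(rec.n_real, rec.n_bg, catalog.total_real, total_bg)
    return catalog


def core_kmers(catalog: KmerCatalog, z_threshold: float = 1.96) -> set[str]:
    """Significant k-mers whose z-score strictly exceeds the threshold."""
    core = {
        km
        for km, rec in catalog.records.items()
        if not math.isnan(rec.z) and rec.z > z_threshold
    }
    if not core:
        log.warning("side %s: no core k-mers at z > %g", catalog.side, z_threshold)
    return core


def write_catalog_tsv(catalog: KmerCatalog, path) -> None:
    """Dump the catalog as TSV: kmer, side, n_real, n_bg, p_real, p_bg, z."""
    with open(path, "w") as fh:
        fh.write("kmer\tside\tn_real\tn_bg\tp_real\tp_bg\tz\n")
        for km in sorted(catalog.records):
            r = catalog.records[km]
            fh.write(
                f"{r.kmer}\t{r.side}\t{r.n_real}\t{r.n_bg}\t"
                f"{r.p_real:.6g}\t{r.p_bg:.6g}\t{r.z:.6g}\n"
            )
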