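"""Evaluation statistics for predicted motif pairs.

* motif distance D(H1, H2): minimum over ungapped alignments (overlap of
  at least 4 columns, both orientations) of the mean per-column Euclidean
  distance between probability columns, scaled by 1/sqrt(2) into [0, 1];
* MPD (motif pair distance): mean over known pairs of the best combined
  distance D(side A) + D(side B) to any predicted pair;
* MPFR (motif pair found ratio): fraction of known pairs whose best
  predicted match has both side distances below 0.5;
* TF-pair derivation from a motif database and motif->TF mapping;
* hypergeometric enrichment of predicted TF pairs in a known set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.stats import hypergeom

from mpchg.motif_assembly import PWM, MotifPair

log = logging.getLogger(__name__)

_SQRT2 = float(np.sqrt(2.0))

#: MPD for an empty prediction set: supremum of D(A) + D(B)
EMPTY_PREDICTION_MPD = 2.0
#: distance below which two motifs are considered a significant match
MATCH_THRESHOLD = 0.5


@dataclass(frozen=True)
class MotifDistanceResult:
    d: float
    best_offset: int
    best_orientation: str  # "forward" | "revcomp"


def motif_distance(h1: PWM, h2: PWM, min_overlap: int = 4) -> MotifDistanceResult:
    """Normalized best-alignment column distance between two PWMs.

    Both orientations of h2 are tried; for each offset with at least
    `min_overlap` aligned columns the mean column Euclidean distance is
    computed over the overlap only, divided by sqrt(2) so identical
    matrices give 0 and disjoint near-indicator columns give ~1.
    """
    m1 = h1.matrix
    best = None
    for orientation, m2 in (
        ("forward", h2.matrix),
        ("revcomp", h2.matrix[::-1, ::-1]),
    ):
        l1, l2 = len(m1), len(m2)
        if min(l1, l2) < min_overlap:
            raise ValueError("PWMs must span at least 4 columns to compare")
        for offset in range(-(l2 - min_overlap), l1 - min_overlap + 1):
            a0 = max(0, offset)
            a1 = min(l1, offset + l2)
            if a1 - a0 < min_overlap:
                continue
            cols1 = m1[a0:a1]
            cols2 = m2[a0 - offset : a1 - offset]
            d = float(np.linalg.norm(cols1 - cols2, axis=1).mean()) / _SQRT2
            if best is None or d < best.d:
                best = MotifDistanceResult(d, offset, orientation)
    assert best is not None
    return best


def _pair_distance(
    known: tuple[PWM, PWM], predicted: tuple[PWM, PWM]
) -> tuple[float, float]:
    da = motif_distance(known[0], predicted[0]).d
    db = motif_distance(known[1], predicted[1]).d
    return da, db


def _predicted_pwms(predicted) -> list[tuple[PWM, PWM]]:
    out = []
    for p in predicted:
        if isinstance(p, MotifPair):
            out.append((p.pwm_a, p.pwm_b))
        else:
            out.append(tuple(p))
    return out


def mpd(predicted, known: list[tuple[PWM, PWM]]) -> float:
    """Mean best combined distance from each known pair to the predictions.

    A predicted pair may serve as the best match of several known pairs.
    With no predictions at all the sentinel maximum (2.0) is returned.
    """
    if not known:
        raise ValueError("known motif pairs must be non-empty")
    preds = _predicted_pwms(predicted)
    if not preds:
        log.warning("no predicted motif pairs: MPD set to maximum (2.0)")
        return EMPTY_PREDICTION_MPD
    total = 0.0
    for kp in known:
        total += min(sum(_pair_distance(kp, pp)) for pp in preds)
    return total / len(known)


def mpfr(predicted, known: list[tuple[PWM, PWM]], d_threshold: float = MATCH_THRESHOLD) -> float:
    """Fraction of known pairs recovered by their best predicted match.

    A known pair counts as found when the predicted pair minimizing the
    combined distance has BOTH side distances strictly below the
    threshold.
    """
    if not known:
        raise ValueError("known motif pairs must be non-empty")
    preds = _predicted_pwms(predicted)
    if not preds:
        return 0.0
    found = 0
    for kp in known:
        dists = [_pair_distance(kp, pp) for pp in preds]
        da, db = min(dists, key=sum)
        if da < d_threshold and db < d_threshold:
            found += 1
    return found / len(known)


@dataclass
class TFPairSet:
    pairs: set[frozenset[str]]
    mode: str  # "all_tfs" | "best_tf"

    def __len__(self) -> int:
        return len(self.pairs)

    @property
    def tfs(self) -> set[str]:
        return set().union(*self.pairs) if self.pairs else set()


def _match_tfs(
    pwm: PWM,
    motif_db: dict[str, PWM],
    motif2tf: dict[str, set[str]],
    mode: str,
    d_threshold: float,
) -> set[str]:
    dists = {
        mid: motif_distance(pwm, db_pwm).d for mid, db_pwm in motif_db.items()
    }
    if mode == "all_tfs":
        ids = [mid for mid, d in dists.items() if d < d_threshold]
    elif mode == "best_tf":
        best = min(dists.items(), key=lambda kv: (kv[1], kv[0]))
        ids = [best[0]] if best[1] < d_threshold else []
    else:
        raise ValueError(f"unknown mode {mode!r}")
    tfs: set[str] = set()
    for mid in ids:
        tfs |= set(motif2tf.get(mid, ()))
    return tfs


def derive_tf_pairs(
    motif_pairs: list[MotifPair],
    motif_db: dict[str, PWM],
    motif2tf: dict[str, set[str]],
    mode: str = "all_tfs",
    d_threshold: float = MATCH_THRESHOLD,
) -> TFPairSet:
    """TF pairs implied by matching each predicted PWM against a motif DB.

    `all_tfs` takes the TFs of every DB motif within the distance
    threshold; `best_tf` only those of the single closest motif (ties on
    distance resolved to the lexicographically smallest motif id). TF
    pairs are the deduplicated cross product of the two sides' TF sets,
    with self-pairs removed.
    """
    if not motif2tf:
        raise ValueError("motif2tf mapping must be non-empty")
    pairs: set[frozenset[str]] = set()
    for mp in motif_pairs:
        tfs_a = _match_tfs(mp.pwm_a, motif_db, motif2tf, mode, d_threshold)
        tfs_b = _match_tfs(mp.pwm_b, motif_db, motif2tf, mode, d_threshold)
        if not tfs_a or not tfs_b:
            log.info("motif pair %s matched nothing on one side", mp.community_id)
            continue
        for ta in tfs_a:
            for tb in tfs_b:
                if ta != tb:
                    pairs.add(frozenset((ta, tb)))
    return TFPairSet(pairs, mode)


@dataclass
class EnrichmentInput:
    """Counts for the hypergeometric enrichment of predicted TF pairs.

    N: TF universe size; M: known TF-pair count; n: number of TFs in the
    predicted pairs; m: number of predicted TF pairs.
    """

    N: int
    M: int
    n: int
    m: int

    def __post_init__(self) -> None:
        if self.n > self.N:
            raise ValueError("predicted TF count exceeds universe size")
        if self.m > self.n * (self.n - 1) // 2:
            raise ValueError("predicted pair count exceeds n(n-1)/2")
        if self.M > self.N * (self.N - 1) // 2:
            raise ValueError("known pair count exceeds N(N-1)/2")


def phyper(x1: int, y1: int, x2: int, y2: int) -> float:
    """Upper-tail hypergeometric probability P(X >= x1).

    X counts how many of x2 draws from a population of y2 fall in a
    marked subset of y1. Evaluated via scipy's log-space survival
    function for numerical stability.
    """
    if min(x1, y1, x2, y2) < 0:
        raise ValueError("arguments must be non-negative")
    if x1 > min(y1, x2):
        raise ValueError(
            f"observed count {x1} exceeds support min({y1}, {x2})"
        )
    return float(hypergeom.sf(x1 - 1, y2, y1, x2))


def enrichment_pvalue(inp: EnrichmentInput) -> float:
    """Enrichment of predicted TF pairs among all pairs of predicted TFs.

    The population is the N(N-1)/2 possible TF pairs of the universe,
    the marked subset the n(n-1)/2 pairs of predicted TFs, the draws the
    M known pairs, and the observation the m predicted pairs.
    """
    return phyper(
        inp.m, inp.n * (inp.n - 1) // 2, inp.M, inp.N * (inp.N - 1) // 2
    )


def read_two_column_tsv(path) -> list[tuple[str, str]]:
    """Parse a 2-column TSV (e.g. motif->TF map, known TF interactions)."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 2:
                raise ValueError(f"expected 2 tab-separated columns: {line!r}")
            out.append((cols[0], cols[1]))
    return out
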