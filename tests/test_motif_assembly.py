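import itertools

import numpy as np
import pytest

from mpchg.community_detect import Community
from mpchg.kmer_stats import KmerCatalog, KmerRecord, enumerate_kmers, revcomp
from mpchg.motif_assembly import (
    PWM,
    Placement,
    PwmScanner,
    align_to_center,
    build_pwm,
    call_motif_pairs,
    community_to_pwm_pair,
    read_meme,
    scan,
    split_and_center,
    write_meme,
)
from mpchg.seq_io import PairedDataset, SequencePair


def indicator_pwm(consensus, info=0.99, name="m"):
    mat = np.full((len(consensus), 4), (1 - info) / 3)
    for i, b in enumerate(consensus):
        mat[i, "ACGT".index(b)] = info
    return PWM(matrix=mat, name=name)


def catalog_for(kmers, side="A"):
    records = {
        km: KmerRecord(km, side, n_real=1, p_real=1.0 / len(kmers)) for km in kmers
    }
    return KmerCatalog(side, len(next(iter(kmers))), records)


class TestSplitAndCenter:
    def test_centers_from_heaviest_pair_edge(self):
        nodes = {("AAATTT", "A"), ("CCCAAA", "A"), ("GGGTTT", "B")}
        comm = Community(
            nodes=nodes,
            fitness=1.0,
            pair_weights={
                (("AAATTT", "A"), ("GGGTTT", "B")): 0.4,
                (("CCCAAA", "A"), ("GGGTTT", "B")): 0.9,
            },
        )
        (kmers_a, center_a), (kmers_b, center_b) = split_and_center(comm)
        assert center_a == "CCCAAA" and center_b == "GGGTTT"
        assert kmers_a == {"AAATTT", "CCCAAA"}

    def test_two_node_community(self):
        comm = Community(
            nodes={("AAATTT", "A"), ("GGGTTT", "B")},
            fitness=0.5,
            pair_weights={(("AAATTT", "A"), ("GGGTTT", "B")): 0.5},
        )
        (ka, ca), (kb, cb) = split_and_center(comm)
        assert ca == "AAATTT" and cb == "GGGTTT"

    def test_one_sided_community_skipped(self):
        comm = Community(nodes={("AAATTT", "A")}, fitness=0.0)
        assert split_and_center(comm) is None

    def test_weight_tie_prefers_lexicographic(self):
        comm = Community(
            nodes={("TTTAAA", "A"), ("AAATTT", "A"), ("GGGTTT", "B")},
            fitness=1.0,
            pair_weights={
                (("TTTAAA", "A"), ("GGGTTT", "B")): 0.7,
                (("AAATTT", "A"), ("GGGTTT", "B")): 0.7,
            },
        )
        (_, center_a), _ = split_and_center(comm)
        assert center_a == "AAATTT"


class TestAlign:
    def test_one_mismatch_offset_zero(self):
        placed = align_to_center({"ACGTAA"}, "ACGTAC")
        assert placed["ACGTAA"].offset == 0

    def test_overlap_shift(self):
        # center suffix GTAC = k-mer prefix, overlap 4 -> offset +2
        placed = align_to_center({"GTACGG"}, "ACGTAC")
        assert placed["GTACGG"].offset == 2

    def test_unrelated_dropped(self):
        placed = align_to_center({"TTTGGG"}, "ACGTAC")
        assert "TTTGGG" not in placed
        assert placed["ACGTAC"].offset == 0

    def test_chained_placement(self):
        # CGTACG relates to the center (shift +1); TACGGA relates to
        # neither orientation of the center, only to CGTACG (shift +2)
        placed = align_to_center({"CGTACG", "TACGGA"}, "ACGTAC")
        assert placed["CGTACG"].offset == 1
        assert placed["TACGGA"].offset == 3

    def test_revcomp_orientation_fallback(self):
        # ATAAGG has no forward relation to CCCTTA, but its revcomp
        # CCTTAT overlaps it by 5 at shift +1
        placed = align_to_center({"ATAAGG"}, "CCCTTA")
        assert placed["ATAAGG"].strand == "-"
        assert placed["ATAAGG"].oriented == "CCTTAT"
        assert placed["ATAAGG"].offset == 1


class TestBuildPwm:
    def test_single_kmer_indicator(self):
        cat = catalog_for({"ACGTAC"})
        pwm = build_pwm({"ACGTAC": Placement(0, "ACGTAC", "+")}, cat)
        assert len(pwm) == 6
        assert pwm.consensus == "ACGTAC"
        assert pwm.matrix.max() > 0.99

    def test_two_kmers_split_column(self):
        cat = catalog_for({"ACGTAC", "ACGTAA"})
        aligned = {
            "ACGTAC": Placement(0, "ACGTAC", "+"),
            "ACGTAA": Placement(0, "ACGTAA", "+"),
        }
        pwm = build_pwm(aligned, cat, center="ACGTAC")
        col = pwm.matrix[5]
        assert col["ACGT".index("C")] == pytest.approx(0.5, abs=0.01)
        assert col["ACGT".index("A")] == pytest.approx(0.5, abs=0.01)

    def test_columns_sum_to_one(self):
        cat = catalog_for({"ACGTAC", "CGTACG"})
        aligned = {
            "ACGTAC": Placement(0, "ACGTAC", "+"),
            "CGTACG": Placement(1, "CGTACG", "+"),
        }
        pwm = build_pwm(aligned, cat, center="ACGTAC")
        assert len(pwm) == 7
        np.testing.assert_allclose(pwm.matrix.sum(axis=1), 1.0, atol=1e-9)

    def test_strict_flank_trim_restores_center_span(self):
        cat = catalog_for({"ACGTAC", "CGTACG"})
        aligned = {
            "ACGTAC": Placement(0, "ACGTAC", "+"),
            "CGTACG": Placement(1, "CGTACG", "+"),
        }
        pwm = build_pwm(aligned, cat, center="ACGTAC", min_flank_coverage=2)
        assert len(pwm) == 6  # the singly covered column 6 is trimmed


class TestScan:
    def test_perfect_match_forward(self):
        pwm = indicator_pwm("ACGTAC")
        ds = PairedDataset([SequencePair("p1", "TTTTACGTACTTTT", "AAAA")])
        hits = scan(pwm, ds, "A", p_threshold=5e-4)
        assert any(h.offset == 4 and h.strand == "+" for h in hits)

    def test_revcomp_hit_on_minus_strand(self):
        pwm = indicator_pwm("ACGTAC")
        ds = PairedDataset([SequencePair("p1", "TTTTGTACGTTTTT", "AAAA")])
        hits = scan(pwm, ds, "A", p_threshold=5e-4)
        assert any(h.offset == 4 and h.strand == "-" for h in hits)

    def test_hits_invariant_under_sequence_revcomp(self):
        pwm = indicator_pwm("ACGTTGCA")
        seq = "TGCAACGTTGCATTGGCCAATT"
        ds1 = PairedDataset([SequencePair("p1", seq, "AAAA")])
        ds2 = PairedDataset([SequencePair("p1", revcomp(seq), "AAAA")])
        bg = np.full(4, 0.25)
        h1 = scan(pwm, ds1, "A", 1e-3, background=bg)
        h2 = scan(pwm, ds2, "A", 1e-3, background=bg)
        remapped = {
            (len(seq) - h.offset - len(pwm), {"+": "-", "-": "+"}[h.strand])
            for h in h2
        }
        assert {(h.offset, h.strand) for h in h1} == remapped

    def test_n_windows_skipped(self):
        pwm = indicator_pwm("ACGTAC")
        ds = PairedDataset([SequencePair("p1", "TTTACGNACTTT", "AAAA")])
        assert scan(pwm, ds, "A", p_threshold=1.0) != []  # N-free windows exist
        offsets = {h.offset for h in scan(pwm, ds, "A", p_threshold=1.0)}
        assert all(off + 6 <= 12 for off in offsets)
        assert not any(3 <= off <= 6 for off in offsets)  # windows over the N

    def test_null_distribution_sums_to_one(self):
        pwm = indicator_pwm("ACGT")
        scanner = PwmScanner(pwm, np.array([0.3, 0.2, 0.2, 0.3]))
        # survival function at the minimum score is the full mass
        assert scanner._pvals[0] == pytest.approx(1.0, abs=1e-9)

    def test_dp_pvalues_match_enumeration_width4(self):
        rng = np.random.default_rng(5)
        mat = rng.dirichlet(np.ones(4), size=4)
        pwm = PWM(matrix=mat)
        bg = np.array([0.2, 0.3, 0.3, 0.2])
        scanner = PwmScanner(pwm, bg)
        for window in itertools.product(range(4), repeat=4):
            s = int(sum(scanner.int_scores[i, b] for i, b in enumerate(window)))
            enum_p = sum(
                np.prod([bg[b] for b in w])
                for w in itertools.product(range(4), repeat=4)
                if int(sum(scanner.int_scores[i, b] for i, b in enumerate(w))) >= s
            )
            assert scanner.p_value(s) == pytest.approx(enum_p, abs=1e-12)


class TestCallMotifPairs:
    def _implanted_dataset(self, rng, n_pairs=60, motif_a="TGGCCAAAAT", motif_b="CTGACTGATG"):
        bases = np.array(list("ACGT"))
        pairs = []
        for i in range(n_pairs):
            sa = "".join(rng.choice(bases, size=80))
            sb = "".join(rng.choice(bases, size=80))
            off = 20
            sa = sa[:off] + motif_a + sa[off + len(motif_a):]
            sb = sb[:off] + motif_b + sb[off + len(motif_b):]
            pairs.append(SequencePair(f"p{i}", sa, sb))
        return PairedDataset(pairs)

    def test_exact_implant_recovered(self, rng):
        # every window of these motifs has a distinct canonical form, so
        # the consensus is recoverable exactly (up to strand)
        motif_a, motif_b = "TGGCCAAAAT", "CTGACTGATG"
        ds = self._implanted_dataset(rng, motif_a=motif_a, motif_b=motif_b)
        cat_a = enumerate_kmers(ds, "A", k=6)
        cat_b = enumerate_kmers(ds, "B", k=6)
        kmers_a = {km for km in cat_a.records if cat_a.records[km].n_real >= 50}
        kmers_b = {km for km in cat_b.records if cat_b.records[km].n_real >= 50}
        nodes = {(km, "A") for km in kmers_a} | {(km, "B") for km in kmers_b}
        pair_weights = {
            ((ka, "A"), (kb, "B")): 1.0 for ka in kmers_a for kb in kmers_b
        }
        comm = Community(nodes=nodes, fitness=1.0, pair_weights=pair_weights)
        pairs = call_motif_pairs([comm], ds, cat_a, cat_b)
        assert len(pairs) == 1
        mp = pairs[0]
        assert mp.n_support == len(ds)
        assert mp.pwm_a.consensus in (motif_a, revcomp(motif_a))
        assert mp.pwm_b.consensus in (motif_b, revcomp(motif_b))

    def test_support_requires_both_sides(self, rng):
        # the chosen B-side k-mer is near-absent from side B: no
        # sequence pair can support the motif pair
        ds = self._implanted_dataset(rng)
        cat_a = enumerate_kmers(ds, "A", k=6)
        cat_b = enumerate_kmers(ds, "B", k=6)
        kmers_a = {km for km in cat_a.records if cat_a.records[km].n_real >= 50}
        absent = {"TTTTTC"}  # not implanted; near-absent from side B
        nodes = {(km, "A") for km in kmers_a} | {(km, "B") for km in absent}
        comm = Community(
            nodes=nodes,
            fitness=1.0,
            pair_weights={((ka, "A"), ("TTTTTC", "B")): 1.0 for ka in kmers_a},
        )
        cat_b.records.setdefault(
            "TTTTTC",
            type(cat_a.records[next(iter(kmers_a))])("TTTTTC", "B", 1, p_real=1e-4),
        )
        pairs = call_motif_pairs([comm], ds, cat_a, cat_b, min_support=1)
        assert pairs == []


class TestMemeIO:
    def test_roundtrip(self, tmp_path):
        pwms = [indicator_pwm("ACGTACGT", name="m1"), indicator_pwm("GGGGCCCC", name="m2")]
        path = tmp_path / "motifs.meme"
        write_meme(pwms, path)
        back = read_meme(path)
        assert set(back) == {"m1", "m2"}
        np.testing.assert_allclose(back["m1"].matrix, pwms[0].matrix, atol=1e-5)
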