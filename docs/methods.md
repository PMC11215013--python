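# Methods

This note documents the model behind `mpchg`, the choices made where the
design was genuinely open, and what the synthetic benchmark does and does
not demonstrate.

## Problem setting

The input is an ordered set of sequence pairs: the i-th record of two FASTA
files forms one pair (side A, "enhancer"; side B, "promoter"). The goal is
a set of motif *pairs* — a PWM per side — such that both motifs tend to
occur within the same sequence pairs, the signature expected of
transcription-factor pairs that cooperate across a chromatin contact.

## Background model

Each side gets its own third-order Markov chain trained on all real
sequences of that side (promoter-side sequences are typically GC-rich, so
the sides are never pooled). Transition counts receive add-one smoothing;
contexts containing N contribute nothing, and generation never emits N.
The initial context of each generated sequence is drawn from the empirical
context distribution so that even short sequences are composition-matched.
Each background sequence has exactly the length of its real counterpart.
Contexts never observed in training fall back to the side's 0-order base
frequencies — at corpus scale (10^5 transitions over 64 contexts) this is
a vanishing correction.

## k-mer statistics

k = 6 by default. Every window without N contributes one count to its
canonical form (lexicographic minimum of the window and its reverse
complement), so a motif and its reverse complement are indistinguishable by
construction. Low-complexity k-mers — one base occupying ≥ k−1 positions —
are excluded before any frequency is computed; this is the mildest rule
consistent with excluding homopolymers.

*Significant* k-mers satisfy p > mean + 1·sd of the side's frequency
distribution (population sd, computed after the low-complexity exclusion;
strict inequality). Frequencies are **not** renormalized after selection:
they remain fractions of the side's full retained-k-mer total, because the
downstream z statistic is defined through those global totals.

*Core* k-mers additionally pass a pooled two-proportion z-test against the
background, z > 1.96 (strict). The standard error uses the global retained
totals (1/Σn_F + 1/Σn_B) rather than per-k-mer trial counts — this is how
the statistic is defined here, and it differs deliberately from a textbook
two-proportion test on Bernoulli windows. A selected k-mer's background
count is looked up (possibly 0), never re-selected by background frequency.

## Composite heterogeneous graph

Nodes are the significant k-mers of both sides.

**Pair edges** (cross-side). The co-occurrence count N(v,u) is the number
of distinct sequence pairs containing both k-mers (multiplicity within one
sequence does not add). On ~500 nt sequences a given 6-mer is present in
roughly a fifth of all pairs, so almost *every* cross-side pair of frequent
k-mers co-occurs somewhere; connecting all of them yields a near-complete
bipartite graph on which any average-weight-penalized density objective
concentrates on one global core (we verified this directly: every greedy
community absorbed all planted motifs regardless of seed). The edge set is
therefore background-corrected with the same logic the method applies to
nodes: an edge is kept only when N exceeds the count expected under
independent presence of the two k-mers, by a one-sided binomial z > 1.96
(the method's significance constant; setting `edge_z=None` restores the
literal "any co-occurrence" rule). Surviving edges are weighted exactly as
defined: min-max-scaled N plus the two endpoints' neighbor-set fractions
L(v)/n_E + L(u)/m_TSS, where L(·) includes the node itself (so it is never
empty) and n_E, m_TSS are the sides' significant-k-mer counts.

**Neighborhood edges** (same-side). Two k-mers are neighbors when they
differ by one mismatch or share an exact suffix–prefix overlap of ≥ 4
bases (the overlap reading matches the downstream merging step; a literal
"four consecutive identical bases inside each k-mer" would connect
unrelated k-mers). The weight is |L_p∩L_q|/|L_p| + |L_p∩L_q|/|L_q| —
intersection, not union, per the similarity semantics. Both relations are
evaluated on canonical strings.

All weights (both edge types jointly) are min-max normalized to [0, 1];
if all weights are equal they are set to 1 so the edges stay usable.

## Dense subgraphs

The fitness of a node set S prices every missing internal edge at the
graph's average edge weight:

    f(S) = Σ_{e ∈ S} ω(e) − (1/(2|E|)) · (n_S(n_S−1) − 2 m_S) · Σ_{e ∈ G} ω(e)

Growth uses the incremental form δ_S(v) = w(v→S) − ω̄ (n_S − deg_S(v)),
asserted at runtime to match a from-scratch recomputation to 1e-9.

Seeding is unified: every community starts from both endpoints of the
maximum-weight *core* pair edge whose endpoints are not yet assigned to any
community (ties: larger total neighbor count, then lexicographic). Growth
adds the adjacent node with the largest strictly positive δ (ties:
lexicographic), which restricts candidates to S's neighborhood — a pure
optimization, since non-adjacent nodes always have δ < 0. Nodes belonging
to no community are discarded as isolated. Communities whose overlap degree
|C_i∩C_j| / min(|C_i|,|C_j|) strictly exceeds 0.5 are merged, largest
overlap first, until all pairwise overlaps are ≤ 0.5; termination is
guaranteed because the community count strictly decreases.

## PWM assembly and validation

Within a community, the endpoints of the heaviest internal pair edge are
the two centers. Same-side k-mers are placed relative to their center by
one-mismatch (offset 0) or best suffix–prefix overlap (longest overlap,
then smallest |offset|); k-mers unrelated to the center chain through
already-placed k-mers, and the rest are dropped. Because canonicalization
maps roughly half of a motif's windows to the opposite strand, a k-mer
whose forward string has no relation is retried as its reverse complement
(forward always preferred — placements that are valid in forward
orientation are never changed).

Each placed k-mer adds its sequence frequency to the base counts of the
columns it covers. The full aligned span is kept by default: the terminal
columns of a cleanly tiled motif are covered by exactly one window *by
construction*, so trimming singly-covered flanks (available via
`min_flank_coverage=2`) truncates every fully recovered motif by one
column per side — fatal for narrow motifs, whose shortened PWMs can no
longer reach the scan threshold (a width-6 PWM's best attainable p-value
is 4⁻⁶ ≈ 2.4e-4 > 1e-4). Columns are normalized with a relative
pseudocount (mass 0.01, uniform) so all probabilities are positive. If the
span degenerates below 4 columns, the center k-mer alone defines the PWM.

Scanning is self-contained (no external binary): log-odds against the
scanned side's 0-order base frequencies, discretized to 1/1000 bit; the
null distribution of the integer score under the background model is
computed exactly by dynamic programming over columns, and a position is a
hit when P(score ≥ s) < 1e-4 (the conventional scanner default; exposed as
`scan_p`). Both strands are scanned; windows containing N are skipped. A
sequence pair supports a motif pair when side A's PWM hits its A sequence
and side B's PWM hits its B sequence; pairs with support below
`min_support` (default 1 — bare existence) are dropped. A useful side
effect of the scan threshold: spurious 2-node communities yield width-6
PWMs that cannot reach p < 1e-4, so they are filtered out for free.

## Evaluation

The motif distance D(H1,H2) is the minimum over ungapped offsets (overlap
≥ 4 columns) and both orientations of the mean per-column Euclidean
distance between probability columns, divided by √2 so D ∈ [0,1]. Several
column-comparison metrics would serve; this one is symmetric by
construction, 0 iff the matrices coincide at some alignment, and
compatible with the 0.5 match threshold used throughout.

MPD = (1/K) Σ_i min_x [D(m_Pi, M_Px) + D(m_Ei, M_Ex)] over the K known
pairs; a predicted pair may serve several known pairs (no uniqueness
constraint — as defined). With no predictions MPD is reported as 2.0, the
supremum of D+D. MPFR counts the known pairs whose *argmin* predicted pair
has both side distances strictly below 0.5.

TF pairs are derived by matching each predicted PWM against a motif
database (MEME minimal format) with D: mode `all_tfs` takes the TFs of all
motifs with D < 0.5, mode `best_tf` those of the single closest motif
(ties: lexicographically smallest id). TF pairs are the deduplicated cross
product of the two sides' TF sets, self-pairs removed. Enrichment uses
p = phyper(m, n(n−1)/2, M, N(N−1)/2), where m is the number of predicted
TF pairs. At desk scale m can exceed the support
min(n(n−1)/2, M), which the implementation reports as an explicit error
rather than returning 0; the acceptance script therefore scores the
well-posed variant (observed = predicted pairs present in the known set).
The TF universe N defaults to the TFs in the supplied motif→TF map and can
be overridden.

## Synthetic benchmark

`simulate_dataset` emulates the paired-motif planting protocol: sequence
lengths are Normal(500, 20) rounded (floored at twice the widest motif),
backgrounds are i.i.d. uniform over ACGT, profiles are random
one-dominant-base matrices (information `info`, widths 8–12) or drawn from
a user MEME file, and each sequence pair independently receives, with
probability `plant_prob` (default 0.8), one uniformly chosen motif pair
whose two *consensus strings* (per-column argmax) replace substrings at
uniform offsets. Consensus (not sampled) implanting is deliberate — it
matches the protocol being emulated. At most one motif pair is planted per
sequence pair. When 2·(number of motif pairs) ≤ (number of profiles) the
pairs form a random perfect matching so every known pair is unambiguous;
beyond that, distinct profile pairs are drawn with reuse.

What the benchmark does *not* emulate: biological background composition
(CpG islands, repeats), motif variants (every implant is the exact
consensus), multiple motifs per pair, and genomic coordinates. Passing it
shows the pipeline recovers clean planted signal at realistic sizes; it
does not bound performance on real chromatin data.

The standard conditions used by the test suite and the acceptance script
are 300 sequence pairs, 10 profiles, 5 motif pairs, info 0.95, plant
probability 0.9; the trend check spans 100/300/600 pairs with 5 seeds
each. These sizes complete in seconds per run while leaving each planted
k-mer ~50-fold enriched over background — comfortably inside the regime
the statistics are designed for.

## Numerical and degenerate-case choices

- Ties broken deterministically everywhere (weight, then neighbor count,
  then lexicographic); reruns with one seed are byte-identical.
- Degenerate min-max (all equal): co-occurrence term 0 in the pair-edge
  weight; all normalized weights 1.
- Pooled proportion 0 or 1 in the z-test: z = 0 (no evidence).
- Scan score discretization at 1/1000 bit: the DP null matches exhaustive
  window enumeration to 1e-12 because both operate on the same integers.
- Hypergeometric tail via scipy's survival function (log-space internally).

## Known limitations

- The edge-level co-occurrence filter is a deliberate deviation from the
  literal "connect on any co-occurrence" rule; without it the greedy
  density objective provably collapses onto one global community on long
  paired sequences (see the graph section). `edge_z=None` restores the
  literal behavior.
- Canonical collapsing makes a motif containing both a k-mer and its
  reverse complement unrecoverable at full width (two windows merge into
  one canonical form); affected plants lose one terminal column.
- Width-6 communities cannot be validated at scan p < 1e-4 at all; this is
  inherent to the threshold, not a bug (an external scanner behaves the
  same way).
- Two statistics (the global-total standard error in the k-mer z-test;
  m = all predicted TF pairs in the enrichment) deliberately differ from
  their textbook analogues; both are flagged above.
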