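# Methods

This note documents the models, algorithms and numerical choices behind
`anchorsv`, what the synthetic data does and does not emulate, and the
design decisions taken where several reasonable options existed.

## Anchor finding

Anchors are maximal unique matches (MUMs): exact matches unique in both
genomes and not extendable on either side. We seed with k-mers
(k = `min_anchor_len`, default 20, valid range 15–31, packed 2 bits/base
into uint64) that occur exactly once in each genome, merge seeds on the
same alignment diagonal, and extend each run to its maximal extent by
direct comparison. Any match containing a both-genomes-unique k-mer is
itself unique, so every reported anchor satisfies MUM semantics. The
converse does not hold: a maximal match that is unique as a whole but
none of whose k-mers is individually unique will be missed. On random
sequence at desk scale this is vanishingly rare; on highly repetitive
real genomes it would matter, and a suffix-array backend would be the
upgrade path. Both query strands are searched; uniqueness is enforced
per searched orientation.

## Chaining and block ranks

Anchors are chained greedily in reference order into maximal runs whose
consecutive members are colinear, same-strand, and within `max_gap`
(default 500 bp) on both genomes; small overlaps (repeats at a junction
make maximal matches overlap) are tolerated up to the same bound. Chains
whose summed anchor length falls below `min_cluster` (default 1 kb) are
discarded. This mirrors greedy cluster formation rather than
optimal-chaining DP: with unique anchors the two coincide except in
adversarial layouts, and the greedy partition is what the randomized
oracle in the test suite checks. Blocks are ranked by midpoint order
along each genome; rank pairs drive translocation detection.

## Indel calling from chain gaps

Walking consecutive anchors along the backbone (the length-weighted
longest increasing subsequence of query order over reference order,
restricted to plus-strand blocks pairing with the dominant partner
chromosome), each gap yields: an insertion where only query sequence is
unaligned, a deletion where only reference sequence is, and — where both
sides have sequence — the net indels of an end-anchored global alignment
(match +1, mismatch −1, gap open −2, extend −1, via Biopython's
PairwiseAligner). Gaps where both sides exceed 20 kb are left uncalled
rather than aligned. Breakpoints are left-aligned through repeat context
(VCF convention), which makes calls canonical and lets truth-set
comparisons demand exact coordinates. An insertion whose sequence equals
the adjacent reference segment is reclassified as a tandem duplication;
the simulator correspondingly redraws insertion sequences that would be
duplications by definition, so truth labels stay unambiguous.

Spans already explained by inversion or translocation calls (padded by
`max_gap`) mask indel calling on both coordinate frames — otherwise a
translocation's source would surface again as a large deletion and its
destination as a large insertion.

## Inversions and translocations

Minus-strand blocks are inversion evidence; runs of them within
`max_gap` merge into one call (the merge distance deliberately reuses
the one stated gap parameter rather than introducing a new one).
Translocations are "nonsequential" blocks: blocks pairing with a
non-dominant chromosome (inter-chromosomal), or dominant-partner blocks
off the length-weighted LIS backbone (intra-chromosomal). Weighting by
anchored length prevents a long resident block being sacrificed to keep
a short moved one. Rank-consistent minus-strand blocks are inversions,
not translocations, because block midpoints — not strand — enter the
LIS.

## Validation filters

Small branch (length ≤ 50 bp): a supporting read must carry a gap op of
the matching kind whose implied breakpoint lies within ±10 bp of the
left-aligned call and whose length agrees within the same tolerance;
acceptance requires strictly more than three such reads. Large branch:
single-end (S) and properly-paired (P) read counts are taken in a window
of one insert mean on each side of the SV span, on both genome
alignments; acceptance requires a two-sided Fisher p < 0.05 on the
(S,P)×(genome) table **and** length > 3 × insert-size s.d. Sidedness and
window size are our choices where the filter definitions leave them
open; the two-genome contrast (rather than a genome-wide background) is
used for the Fisher table. The insert s.d. may be given or estimated
from properly-paired records after trimming at the 1st/99th percentiles.

A structural consequence worth stating plainly: candidates with length
in (50, 3 × s.d.] can never be accepted — too long for the small branch,
too short for the large one. At the default s.d. of 50 bp this dead zone
is (50, 150]. The validation study scenarios therefore draw truth
lengths on both sides of it (exact composition per run: 50 short ≤ 10 bp,
5 mid 11–50 bp, 5 large 151–2,000 bp per SV type); this reflects the
filter's structure, not a tuning of the generator toward any outcome.

## The simulator

`generate_reference` produces uniform-random sequence at a configurable
GC fraction with non-overlapping gene models (5′UTR, ≥ 2 exons, GT..AG
introns, 3′UTR; CDS a multiple of 3 starting ATG, ending a stop, no
internal stop; both strands). `implant_variants` reserves, for each
event, its reference footprint plus `min_separation` (default 2 kb) of
clean flank on each side, and stays `telomere_guard` away from
chromosome ends — so truth recall can be exactly 1 in clean tests, and
anchors always re-form between events. Translocations are
excision+reinsertion (not reciprocal); inversions are in-place reverse
complements; duplications are tandem copies.

`simulate_alignments` assigns reads placements through the known
derived→reference map instead of running a mapper: reads inside colinear
(or inverted, or moved) segments place gaplessly; reads crossing a small
(≤ 50 bp) indel junction with at least `min_overlap` (10 bp) flank on
each side become gapped alignments carrying the truth gap op; reads
crossing large-SV junctions are dropped and their mates emitted
single-end; pairs are properly paired when mates land on one chromosome
within [2 × read length, insert mean + 5 s.d.]. A configurable 0.5 % of
reads are re-placed uniformly at random as single-end records so the
validation filters face a nonzero null. Insert sizes are normal
(mean 350 bp, s.d. 50 bp — a typical short-insert paired-end library),
truncated below at twice the read length (100 bp).

What the simulator does **not** emulate: sequencing errors and quality
scores, repeat-induced mapping ambiguity, GC coverage bias, chimeric
reads, and reciprocal or nested structural events. Passing tests
therefore demonstrate the correctness of the algorithms under clean
evidence, not robustness to real-library artefacts.

## Window statistics and the permutation test

Windows are non-overlapping tiles: fixed 1 Mb or 500 kb, or 1,000 equal
windows per chromosome with the last window absorbing the remainder. An
SV is assigned to the window containing its start; density is count per
Mb. The telomeric set is the outer 10 % of windows at each end (20 %
total, split symmetrically); the fold is the ratio of mean telomeric to
mean interior density with windows pooled across chromosomes
(per-chromosome folds are also reported). The permutation null shuffles
window densities across positions within each chromosome — preserving
per-chromosome totals — and p = (1 + #{fold* ≥ fold}) / (1 + n_perm),
never smaller than 1/(n_perm + 1). Shuffling densities rather than raw
counts differs only in the remainder-absorbing last window. Permutations
are vectorized (one `permuted` call per chromosome over an
n_perm × n_windows matrix), so a 10⁶-permutation run on a real-size
genome is minutes, and the calibration suite (200 replicates × 2,000
permutations) runs in seconds.

Mann–Whitney U uses midranks for ties, exact enumeration for
n₁ + n₂ ≤ 12 without ties and the tie- and continuity-corrected normal
approximation otherwise (delegated to scipy; an exhaustive
rank-assignment oracle cross-checks it in the tests). Fisher's exact
test is the standard two-sided hypergeometric sum (scipy), with p = 1 by
convention when any margin is zero; an exact integer enumeration oracle
cross-checks all tables with margins ≤ 30. The disease index is the
standard weighted-grade summary DI = 100 × Σ(g·n_g)/(4N) over grades
0–4.

## Annotation

Regions follow the precedence exonic-CDS > 5′UTR > 3′UTR > intronic >
upstream1kb > downstream1kb > intergenic, with flanks measured
strand-aware from the transcript ends (UTRs included); the flank width
is configurable (default 1 kb). An SV overlapping several genes yields
one annotation per gene. Coding effects: a net CDS length change not
divisible by 3 is a frameshift; otherwise the variant is spliced into
the CDS and both versions translated — premature stop → stop_gain, lost
terminal stop → stop_loss, else inframe. SVs within 2 bp of an intron
boundary are tagged `splice_region` without consequence prediction; SVs
engulfing a whole gene are tagged `gene_loss`. Expression flags use
|log₂FC| ≥ 1 and p ≤ 0.05, both boundaries inclusive.

## Population logic

Merging is single-linkage over same-type calls with breakpoints within
`pos_tol` (100 bp) and relative length difference within `len_tol`
(0.2); the merged locus takes median breakpoints and length, which makes
merging idempotent. Loci need ≥ 10 present accessions. Single linkage
means a chain of pairwise-close calls merges even when its ends are far
apart — documented behaviour, checked against an exhaustive partition
oracle. MAF is min(f, 1−f) of the presence frequency over non-missing
accessions; calls below the depth floor become missing before the
missing-ratio and MAF filters. "Acquired" loci require ≥ 51 % frequency
in the modern cohort **and** < 51 % in the early cohort; the early-side
condition is a package choice (configurable) — the modern-side rule
alone would also flag loci common in both cohorts. Introgression
overlap requires same type and chromosome with reciprocal overlap ≥ 0.5
or both breakpoints within `pos_tol`. The priority gene count takes,
per family, the maximum count over source genomes, attributed to the
highest-priority source attaining it.

## Reference study scenarios

The discovery benchmark uses a 5-Mb, four-chromosome (2 A + 2 D) pair
with 200 implanted events (100 INS, 60 DEL, 20 INV, 10 TRA, 10 DUP;
indel lengths a 70/30 mixture of short geometric ≤ 10 bp and uniform
11–5,000 bp; INV/TRA/DUP 2–5 kb) — large enough to exercise block
splitting and multi-chromosome ranking, small enough that the whole
pipeline runs in well under a minute per comparison. The validation
benchmark uses a 1.4-Mb pair at 30× simulated coverage with 120 indels
and 1,000 randomly placed decoys kept clear of implanted neighbourhoods
(a decoy coinciding with a real variant would not be false). The
calibration benchmark uses 200 replicate null datasets of 1,000 windows
at 2,000 permutations each. These sizes are the package's reference
conditions; all are configurable.

## Known limitations

- Anchor uniqueness is k-mer-seeded (see above); repeat-dense genomes
  need a suffix-structure backend.
- Nested, overlapping or reciprocal rearrangements are neither simulated
  nor resolved; each call assumes locally clean flanks.
- Inversion calls require the inverted segment to carry at least
  `min_cluster` of anchored sequence; inversions shorter than ~1 kb are
  invisible to the block classifier.
- The large-branch validation dead zone (50, 3 × insert s.d.] is
  inherent to the filter pair.
- Population large-SV discovery from raw reads (read-pair/split-read
  callers, local assembly) is out of scope; the package consumes
  per-accession call sets and implements the merge/filter/cohort logic.
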