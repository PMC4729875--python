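# Methods

This note documents the models and procedures implemented in `retrocall`,
the defaults chosen where the design was genuinely open, and what the
synthetic-data generator does and does not emulate.

## Coordinates and conventions

All coordinates are 0-based, half-open. An insertion point is the index of
the first base of the 3′ genomic flank. The L1 endonuclease motif is written
5′-TTTT/AA-3′ with cleavage between positions 4 and 5; both strands are
scanned, so a top-strand motif occupies `[p−4, p+2)` around the insertion
point `p` and a bottom-strand motif occupies `[p−2, p+4)`. Motif scores are
minimum Hamming distances over both strand readings and are therefore
strand-symmetric.

## Synthetic data generator

The generator emulates the *output* of a capture-sequencing experiment —
aligned junction amplicon records — not the physical assay. Its defaults
describe the study conditions the downstream modules are tested under:

* **Genome**: i.i.d. nucleotides at configurable GC (default 0.41, the
  human genome-wide value), split over `n_chromosomes`; non-overlapping
  gene models with strand-aware TSS.
* **Consensus library**: one synthetic consensus per subfamily (L1-Ta,
  L1 pre-Ta, AluYa5, AluYb8, SVA_E, plus an LTR negative control) at
  scaled-down lengths (1200/300/700/500 bp). Subfamilies of a family share
  a backbone and differ at 4 of 8 diagnostic positions spread along the
  element. The sequences are deterministic random DNA, not biological
  consensus sequences: every algorithm downstream treats them opaquely, so
  their composition is irrelevant to what the tests demonstrate, and the
  scaled lengths keep alignment costs proportionally small.
* **Insertion structure**: per family, fractions of full-length events
  (L1-Ta default 0.5, mirroring the high full-length incidence reported in
  reprogrammed cells), twin-priming among truncated events (0.25), and
  endonuclease-independent integrations (0.1). TSDs of 4–20 bp, pure-A
  poly-A tails of 10–60 bp, 1–2 untemplated 5′ G nucleotides on full-length
  events (probability 0.15), a 25 bp random spacer between the inverted
  segment and the element body in half of twin-priming events, and 3′
  truncation within the final 40 consensus bases for endonuclease-
  independent events.
* **Amplicons**: each junction side emits `Poisson(depth × VAF)` unique
  amplicons whose alignment starts are jittered uniformly within ±30 bases
  of the junction (resampled to distinct starts); PCR duplicates replicate
  a unique amplicon with geometric multiplicity (mean `1/(1−duplicate_rate)`,
  default rate 0.15). Reads are 150-mers, matching common paired-end
  read lengths.

**Junction disambiguation.** The generator keeps its ground truth
well-defined by construction: consensus sequences never start with G (so
untemplated G additions cannot be absorbed into the element body), their
final 20 bases are A-free (so a planted poly-A tail has a sharp boundary),
spacers and 3′ truncation points are resampled so that the flanking bases
cannot extend an exact alignment across a junction by chance, and
untemplated additions are skipped when the adjacent flank base equals the
added base. Real insertions do carry such intrinsically ambiguous junctions;
for them no annotator could recover "the" truth, so the round-trip tests
deliberately measure annotator correctness on resolvable cases only.

What the generator does **not** model: sequencing errors and base
qualities, raw reads and alignment, chimeric amplicons, reference-genome
repeat structure, transductions, or target-site deletions. Passing tests
therefore demonstrate the correctness of the downstream logic under clean
alignments, not robustness to upstream noise.

## Insertion calling

A *unique amplicon* is a distinct genomic alignment start per (junction
side, family, sample) after duplicate collapse — alignment-start identity
being the standard PCR-duplicate proxy. Unique amplicons are clustered by
single linkage along each chromosome within a 200 bp window (junction
amplicons of one event fall within an insert-size-scale neighbourhood); a
cluster becomes a call iff it has ≥ 2 unique amplicons with maximum
pairwise start separation ≥ 5 nt. Separation is measured on alignment
starts. The per-side junction coordinate is the maximum-multiplicity member
start with ties broken toward the 5′-most; the insertion-point estimate
used for matching is the 3′ junction start when present, else the 5′
junction start shifted by the read length. Calls may be single-sided.
Family is assigned by majority vote; subfamily by diagnostic-position
matches against each subfamily consensus, with ties reported as
`unresolved`. Catalog matching requires the same family within ±100 bp
(typical TSD plus breakpoint uncertainty); the window is a flag.

## De novo filter cascade

All four filters are always evaluated and every violated filter is
recorded; a call is de novo iff the failed set is empty. Presence matching
across samples uses the catalog window (±100 bp, same family). The
earlier-passage filter applies along earlier→later passage edges of hESC
lines only — presence only in a later passage is compatible with an
insertion acquired during cultivation — and two passages of one line count
as a single line for the recurrence filter.

## Hallmark annotation

TSD detection is exact-match (longest left-flank suffix equal to a
right-flank prefix, ≤ 30 bp); blunt junctions return the empty string. The
poly-A tail is the maximal 3′-terminal tract tolerating ≤ 1 non-A per 20
scanned bases, ending on an A. The inserted sequence is aligned to each
candidate subfamily consensus in both orientations with a local affine-gap
aligner (match 2, mismatch −3, open −5, extend −2); the best orientation
canonicalises antisense insertions before parsing. Alignment boundaries are
then refined to the outermost exact 10-mer anchor, which removes chance
mismatch-bridged extensions of a few bases at junctions — without this the
truncation offset wobbles by 1–4 bp in roughly 1% of clean events. An
unaligned 5′ prefix longer than 10 bp is tested as a twin-priming inversion
(reverse-complement aligned to the consensus; the unaligned gap between
inverted segment and body is the spacer); a short prefix (≤ 6 bp) is
reported as untemplated addition; an empty prefix allows 1–5 bp of
flank/element microcomplementarity, so untemplated bases and
microcomplementarity are mutually exclusive at a junction. Full length
means a truncation offset ≤ 3 consensus bases (accommodating untemplated
additions) and no inversion. Endonuclease dependence is scored as ≤ 2
mismatches to TTTT/AA ("resembling" the motif); the budget is a flag.

## Sensitivity model and rate estimator

Subsampling uses per-read Bernoulli thinning (not without-replacement
draws): it matches random library sampling at library scale and admits the
closed-form check that an insertion with *k* unique supporting amplicons is
detected at depth *s* with probability `1−(1−s)^k − k·s·(1−s)^(k−1)`.
Within one replicate a single uniform draw per read is thresholded at every
grid depth, so each replicate's detection curve is monotone by construction.
Defaults follow the survey: a 1% grid with 10 samplings per percentile and
the ≥ 2 unique reads detection rule.

The composition `FN(v) = 1 − d(v)·(1 − FN_baseline)`, with all four
families (including LTR) in the count-weighted mean, reproduces the printed
30.5%/94.4% figures from the printed per-family inputs and is adopted as
the model; the printed weights (214, 1411, 53, 14) and detection fractions
ship as documented defaults and are recomputed from data when call sets are
supplied.

The per-line estimator sums `1/p̄_i` over observed de novo insertions,
where `p̄_i` is the mean of insertion *i*'s subsampled detection curve over
grid depths in `[vaf_floor, 1]` (floor 5%: lower-frequency events are not
considered), multiplied by the baseline capture success `1 − FN_baseline`.
The per-cell extrapolation multiplies the corrected per-line count by the
mean VAF of the observed insertions (each insertion is carried by a
fraction ≈ its VAF of cells). Both steps are model-dependent
interpretations and are isolated in `estimate_insertion_rate` for easy
revision. Under the package's default study conditions (depth 40, true VAFs
uniform on the 5–100% grid) the estimator's expected relative error is
within ±20%, which the replicated recovery test verifies; insertions with
zero estimated detection probability are uncorrectable and are excluded
with a warning.

## Positional bias test

The statistic is the mean percentile of gene length from the TSS over
intragenic insertions (strand-aware; an insertion in overlapping genes
contributes its minimum percentile, logged when triggered). The null draws
positions uniformly over the intragenic genome — gene chosen
length-proportionally, position uniform within the gene — because a
"random genomic coordinate conditioned on landing in a gene" is exactly
that distribution; a per-gene-uniform alternative sits behind a flag. The
p-value is `k/N` with exceedance defined as a permuted mean ≤ the observed
mean; with the reported counts (k = 6000, N = 10⁶) this rule gives
p = 0.006 exactly. Genes are put in canonical order before sampling so the
result is invariant to annotation order under a fixed seed.

## Numerical and engineering choices

Every stochastic operation takes an explicit `numpy` generator; identical
configurations and seeds give byte-identical outputs, which the manifest
checksums make observable. Problem sizes in the test suite are scaled to
desk hardware: 100–600 kb genomes, scaled-down consensus lengths, 500-event
hallmark round trips, 50-replicate rate recovery, and 200 null simulations
at 10⁴ permutations for the uniformity check. Degenerate inputs are
defined, not fatal: zero genes give an empty annotation, blunt TSDs return
the empty string, families with no early calls are reported as missing
rather than zero concordance, and malformed catalog records are skipped
with a logged count.

## Known limitations

* The hallmark annotator reports single-sided or unalignable structures as
  unresolved; it does not infer genomic deletions at the integration site,
  nor 5′/3′ transductions.
* The rate estimator inherits the survey's small-sample caveats: with few
  observed insertions the inverse-probability sum has heavy-tailed error,
  and the per-cell extrapolation assumes VAF measures the carrying cell
  fraction.
* The simulator's clean-alignment assumption means false-positive behaviour
  under alignment noise is out of scope; the no-false-positive test is a
  statement about the caller's logic, not about real libraries.
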