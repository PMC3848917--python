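# Methods

This note records the models, conventions and design choices behind
`dupstruct`, in the order the pipeline applies them.

## Gene models and inputs

A gene is represented by one transcript: the one with maximal summed CDS
length, ties broken by lexicographically smallest transcript id. "Longest"
is deliberately CDS-based, not genomic-span-based, because every downstream
measure is coding-region-based; for the same reason the exon count is the
*coding*-exon count of the chosen transcript. Coordinates are 1-based
inclusive (GFF3 convention). Strand is carried but unused: all positional
criteria operate on gene order, which is orientation-agnostic. At load
time every gene must satisfy |CDS| = 3·|protein| (or 3·(|protein|+1) with
a terminal stop); inconsistent records are rejected, not repaired.

Homology hits are directed BLAST-style records; self-hits are removed and
duplicate (query, subject) rows collapsed to the minimal E-value, so the
hit set is independent of input row order.

## Mode classification

The classifier applies, in order: TE exclusion → hit filtering → WGD
label intake → tandem → proximal → transposed. Each removal step operates
on the pairs the previous steps left behind, so the emitted mode sets
partition the candidate pairs.

* **Hit filtering**: E-value < 10⁻¹⁰ (strict) and, per query, the top
  five subjects by ascending E-value (ties: descending bitscore, then
  subject id). Filtering is per-query; a pair remains a candidate if the
  hit survives in either direction, which avoids asymmetric loss from the
  per-query quota. TE genes are excluded *before* the top-five rule.
* **WGD pairs are inputs**, not inferred: α/β/γ pair lists are taken as
  given and override every computed mode. A pair appearing in two WGD
  lists is an input inconsistency and a hard error.
* **Tandem**: both genes on one chromosome with order-index gap 1 (order
  indices are assigned after TE exclusion).
* **Proximal**: same chromosome, gap ≥ 2, and fewer than ten intervening
  genes *not paralogous to either member* (paralogous = connected by a
  filtered hit). Intervening paralogs do not count toward the limit — a
  gap consisting entirely of paralogs (e.g. an expanding tandem array)
  still yields a proximal pair.
* **Colinearity**: anchors (focal gene, outgroup homolog) are chained per
  chromosome pair by dynamic programming; a chain may step 1–25 positions
  on both genomes at once, in either orientation on the outgroup side.
  Chains of ≥ 5 anchors become blocks; anchors join at most one block
  (greedy extraction by anchor count, ties by earliest focal start). The
  defaults (max_gap 25, min 5 anchors) are the conventional
  colinearity-detection settings; both are configurable, and the contract
  is the block definition, not any specific external tool.
* **Ancestral vs novel**: a focal gene is ancestral if it is anchored in
  ≥ 1 block against ≥ 1 outgroup of the active set (*any-outgroup* rule).
  Colinearity with even one outgroup proves the position predates that
  divergence. The rule also makes epoch dating self-consistent: a copy
  transposed *before* the nearest outgroup's divergence is colinear with
  that outgroup at its new position, hence ancestral under the full
  outgroup set, hence correctly excluded from the recent-transposition
  set.
* **Transposed + epochs**: among the remaining pairs, a pair is
  transposed iff exactly one member is ancestral; the ancestral member is
  the parental locus. The test is run twice — once with all outgroups,
  once with only the distant ones — and the set difference contains the
  transpositions older than the nearest outgroup. Epoch labels are
  configuration strings; no dates are computed.

## Structural divergence

Proteins are aligned globally with affine gap penalties (BLOSUM62, gap
open 10, extend 0.5; a length-L gap costs 10 + 0.5·(L−1)). Terminal gaps
are penalized like internal ones by default (an end-gap-free option
exists), and **terminal gaps count as indels**: a coding-length difference
necessarily surfaces as a terminal gap, and dropping it would silently
discard that signal. Non-standard residues score 0 (treated as X);
terminal `*` is stripped. Among co-optimal alignments the aligner's first
traceback is taken, with the input pair canonically ordered so that
swapping the arguments returns the row-swapped identical alignment.
Pre-computed alignments (aligned FASTA, `<A>__<B>.afa`) can be imported
instead; all metrics are aligner-agnostic.

Units: CDS and exon-length differences are in nucleotides; indel lengths
in alignment columns (amino acids). Differences are absolute values;
signed comparisons live only in the parental/transposed asymmetry report,
where a gap in a copy's row is attributed to that copy (structural absence
in it), "equal" meaning exact equality for integer features and
|Δ| < 10⁻⁹ for the real-valued exon measure.

## Ka/Ks (NG86)

The protein alignment is back-translated codon-by-codon (terminal stops
dropped; a codon that does not translate to its aligned residue is an
error). Columns with a gap or an ambiguous base in either row are excluded
from both site and difference counts. The estimator is Nei–Gojobori
(1986): per codon, the synonymous site count is the fraction of the nine
single-base neighbours that are synonymous, normalized so each codon
contributes exactly 3 sites; changes to stop codons count as
non-synonymous (the convention of the standard implementations, which the
test suite cross-checks against). Differences between codons are averaged
with equal weight over all minimal mutation pathways, skipping pathways
through stop intermediates (falling back to all pathways if every one is
blocked). Jukes–Cantor correction is applied to pS and pN; a proportion
≥ 3/4 makes the corresponding rate undefined. Undefined rates propagate as
missing values and the affected pairs are dropped listwise from analyses
that need them — never coerced to 0. ω = Ka/Ks is undefined when Ks is 0
or undefined. The estimator is pluggable: any callable from codon
alignment to rate estimate can replace it downstream.

NG86 was chosen over likelihood-style estimators because it is fully
specified by closed formulas and hand-checkable; every downstream
comparison is rank- or correlation-based, which is insensitive to the
modest absolute shifts between counting estimators.

## Statistics

* Wilcoxon rank-sum: exact two-sided p by enumeration when both samples
  are ≤ 8 and tie-free; otherwise normal approximation with tie-corrected
  variance and continuity correction. Degenerate all-equal input returns
  p = 1 with a flag.
* Pearson correlation: two-sided p from the t-transform with n − 2 df.
* Family contrast: Welch's unequal-variance t-test (the family and the
  genome-wide population differ in variance by construction). A pair
  belongs to the family if *either* member is listed (configurable to
  both); the population deliberately includes the family's own pairs,
  matching a comparison against "all duplicate pairs" rather than the
  complement.
* Mode contrasts restrict WGD to the youngest (α) event and transposed
  pairs to the recent epoch, so that age does not confound the mode
  comparison; epoch contrasts group α/β/γ and recent/old, plus a
  five-group Ka comparison (α, β, recent transposed, γ, old transposed).
* No multiple-testing adjustment: raw p-values at α = 0.05, stated in the
  report output.

## The synthetic-data generator

The generator emulates the statistical structure the analysis assumes,
with truth labels for every planted event. Defaults (the shipped
`study_conditions.yaml`): 5 chromosomes × 400 genes of 120–400 codons with 1–12
coding exons; outgroups at synonymous depths 0.45 / 1.2 / 1.5 with 2%
anchor rearrangement noise; 60/45/35 WGD α/β/γ pairs at target Ks
0.35/0.8/1.8, 60 tandem (Ks 0.15), 50 proximal (0.20), 60 recent
transposed (0.30) and 50 old transposed (0.80) pairs; indel rates graded
by mode (0.001 / 0.005 / 0.013 / 0.025 events per aa site per copy,
geometric lengths with mean 2.5 codons); transposed copies truncated with
probability 0.6 by 25% of their CDS and evolving under relaxed selection
(ω ≈ 1 vs 0.25 genome-wide); a 15-pair high-indel family (rate ×3); 4% TE
decoys; 400 background hits above the E-value cutoff; 20-sample
expression profiles whose noise grows with the pair's applied structural
divergence (coupling 0.15 per indel event).

Three modeling choices deserve emphasis:

* **Distance-targeted substitution.** `evolve_cds` places the
  JC-expected number of observed synonymous and non-synonymous single-base
  differences for the requested Ks (at distinct codons; at extreme
  divergence additional changes stack onto already-substituted codons), so
  a counting estimator recovers the dial by construction (round-trip error
  < 1% at Ks ≤ 1). A mechanistic per-site mutation process was evaluated
  and rejected: the Jukes–Cantor correction inside NG86 is biased for
  2-fold-degenerate sites under such a process (20–45% at Ks = 1), which
  would decouple the dial from the quantity it is meant to control.
* **Epochs on the Ks axis.** A duplicate copy is present (anchored) in an
  outgroup exactly when its event's target Ks exceeds the outgroup's
  divergence depth. Old transpositions are therefore colinear with the
  nearest outgroup at their novel position — precisely the configuration
  that makes epoch recovery by outgroup subtraction well-posed.
* **Truncation bias.** The transposed copy loses a terminal, codon-aligned
  fraction of its CDS; its exon count shrinks *sub*-proportionally
  (ceiling, minimum 1), so the truncated copy's average exon length can
  only shrink or tie. A floor rule would paradoxically lengthen the
  surviving exons for most exon counts and invert the asymmetry the dial
  exists to encode.

What the generator does **not** emulate: intron/UTR sequence, real codon
usage, frame-shifting indels (all indels are codon-aligned and stop-free),
BLAST score statistics (E-values are drawn decreasing in divergence, not
computed from alignments), gene families larger than pairs, and gene loss
after duplication. Consequently, passing tests demonstrate that the
pipeline recovers planted signal of realistic magnitude and direction —
not that real genomes contain such signal. One known real-data pattern is
deliberately outside the default regime: with a single per-mode indel-rate
dial, indel *count* and indel-*length* measures order the modes the same
way, so a regime where WGD pairs have many-but-short indels (more indels
than tandem/proximal yet smaller length differences) is not encoded.

## Numerical conventions and degenerate inputs

Alignment-inferred indel counts are exact only below substitution
saturation: at ≲ 60% amino-acid identity (γ-WGD-level divergence) the
optimal alignment of two equal-length, heavily substituted proteins can
contain balanced gap runs with no true indel behind them (coding-length
difference stays 0). The zero-indel null-process property is therefore
validated at Ks ≤ 0.5, ω = 0.25. Other conventions: expression divergence
is undefined for zero-variance profiles (pair excluded, logged); profiles
shorter than 3 samples are rejected; Wilcoxon p on all-tied data is 1;
empty outgroup sets, empty families, and pairs in two WGD lists are hard
errors; order-index ties (identical start) break deterministically by end
coordinate then gene id; every simulated dataset is byte-identical under a
fixed seed.

## Problem sizes

Shipped study conditions use a ~2,360-gene genome (2,000 ancestral + 360
duplicate copies) and 360 labeled pairs; classifier validation uses ten
seeds, trend/asymmetry analyses five, and oracle checks 1,000 alignment
trials, 50 estimator-agreement pairs, 600 Ks round-trip pairs and 1,000
null replicates per statistical test. A full end-to-end run takes a few
seconds on one CPU.
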