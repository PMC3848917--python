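# dupstruct

Structural divergence between duplicated genes, by mode of duplication.

Duplicate gene pairs arise by whole-genome duplication (WGD) or by
single-gene mechanisms — tandem and proximal duplication on the same
chromosome, or transposition of a copy to a new chromosomal position. The
two copies then diverge not only in nucleotide sequence (Ka, Ks) and
expression, but in *gene structure*: coding-region length, exon
configuration, and insertions/deletions. `dupstruct` is a tested pipeline
for asking how structural divergence differs among duplication modes and
epochs, how it relates to substitution rates and expression divergence, and
whether particular gene families (e.g. the NBS-LRR disease-resistance
family, notorious for transposition) diverge faster than the genome
average.

The pipeline covers:

* **Mode classification.** From an all-vs-all protein homology table
  (E-value < 10⁻¹⁰, top five non-self hits per gene, TE-related genes
  excluded), pairs are classified in removal order: WGD pairs are taken
  from input lists (α/β/γ events); **tandem** pairs are hits between
  consecutive genes; **proximal** pairs are hits between genes on one
  chromosome separated by fewer than ten non-paralogous genes;
  **transposed** pairs join an *ancestral* locus (colinear with at least
  one outgroup genome, found by dynamic-programming anchor chaining) and a
  *novel* locus. Running the ancestral test with two outgroup sets and
  subtracting dates each transposition: pairs transposed relative to all
  outgroups are recent; those transposed only relative to the distant
  outgroups are older than the nearest outgroup's divergence.
* **Structural divergence.** Each pair's proteins are globally aligned
  (Needleman–Wunsch, affine gaps, BLOSUM62, open 10 / extend 0.5); maximal
  runs of `-` in either row are indels (terminal gaps included). Four
  measures per pair: |ΔCDS length| (nt), |Δ average coding-exon length|
  (nt), indel count, and maximum indel length (aa), plus per-copy indel
  statistics for the parental-vs-transposed asymmetry analysis.
* **Substitution rates.** The protein alignment is back-translated to a
  codon alignment and Ka/Ks estimated with the Nei–Gojobori (1986)
  counting method: fractional site counts, equal-weight averaging over
  minimal mutation pathways, Jukes–Cantor correction
  d = −(3/4)·ln(1 − (4/3)p); p ≥ 3/4 is reported as undefined
  (saturation), never as 0.
* **Statistics.** Expression divergence is 1 − r (Pearson correlation of
  expression profiles). Mode/epoch contrasts use two-sided Wilcoxon
  rank-sum tests between consecutive groups (exact by enumeration for
  small tie-free samples); structure–rate and structure–expression
  relationships use Pearson correlation with the t-transform p-value;
  the family contrast uses Welch's t-test. Raw p-values at α = 0.05.
* **Synthetic genomes with truth labels.** A genome-evolution simulator
  generates a focal genome plus outgroups at different divergence depths,
  applies duplications of every mode with known labels, evolves each pair
  to a target Ks with mode-specific indel processes and a truncation bias
  on transposed copies, and emits every input file the pipeline consumes —
  so the whole analysis is testable end-to-end without downloads.

## Worked example

Run the whole pipeline on the shipped study conditions (a ~2,000-gene
genome, three outgroups, 360 duplicate pairs):

```bash
dupstruct run-all --seed 7 --out-dir demo
```

which prints

```
run complete; pairs by mode: {'proximal': 50, 'tandem': 60,
 'transposed_old': 48, 'transposed_recent': 62, 'wgd_alpha': 60,
 'wgd_beta': 45, 'wgd_gamma': 35}
```

(the generator planted 50 old transpositions; two fell within the
rearrangement noise of the nearest outgroup and were dated recent).
`demo/report/mode_medians.tsv` then holds the per-mode medians of the four
measures among age-comparable recent duplicates:

```
                wgd_alpha  tandem  proximal  transposed_recent
d_cds_len             0.0     9.0      13.5              100.5
d_avg_exon_len        0.0     1.24     2.25                4.73
n_indels              0.0     2.0      5.5                11.0
max_indel_len         0.0     3.0      5.0                23.0
```

— the WGD < tandem < proximal < transposed ordering, with every
consecutive Wilcoxon contrast significant (`mode_contrasts.tsv`).
`asymmetry.tsv` shows the directional bias of transposition: the parental
copy has the longer coding region in 75% of transposed pairs and the
longer exons in 68%, while the transposed copy carries more indels (65%)
and the longer maximum indel (76%). `family_test.tsv` flags the planted
high-indel family (indel count: family mean 16.8 vs population 5.7,
Welch t = 8.9, p = 1.6 × 10⁻⁷), and `correlations_expression.tsv` shows
all four structural measures positively correlated with expression
divergence (e.g. indel count: r = 0.85, p ≈ 10⁻¹⁰¹).

Individual stages are available as `dupstruct
simulate|classify|structdiv|rates|report`, each reading and writing plain
TSV/FASTA files; `--help` lists the thresholds (all default to the
standard criteria above).

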