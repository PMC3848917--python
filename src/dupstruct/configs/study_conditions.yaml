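# Shipped study-condition configuration.
#
# A ~2,000-gene focal genome (5 x 400) with three outgroups at increasing
# divergence depths (Ks units). Duplication events carry age-graded target
# Ks and mode-graded indel rates (WGD-alpha < tandem < proximal <
# transposed), plus a truncation bias on transposed copies and a
# designated high-indel gene family.
simulation:
  n_chromosomes: 5
  genes_per_chromosome: 400
  gene_length_codons: [120, 400]
  exon_count_range: [1, 12]
  omega: 0.25
  te_fraction: 0.04
  n_noise_hits: 400
  transposed_truncation_prob: 0.6
  transposed_truncation_fraction: 0.25
  outgroups:
    brassica: {divergence_depth: 0.45, rearrangement_rate: 0.02}
    populus: {divergence_depth: 1.2, rearrangement_rate: 0.02}
    vitis: {divergence_depth: 1.5, rearrangement_rate: 0.02}
  recent_outgroups: [brassica, populus, vitis]
  broad_outgroups: [populus, vitis]
  events:
    wgd_alpha: {count: 60, target_ks: 0.35, indel_rate: 0.0010, indel_length_p: 0.4}
    wgd_beta: {count: 45, target_ks: 0.80, indel_rate: 0.0030, indel_length_p: 0.4}
    wgd_gamma: {count: 35, target_ks: 1.80, indel_rate: 0.0060, indel_length_p: 0.4}
    tandem: {count: 60, target_ks: 0.15, indel_rate: 0.0050, indel_length_p: 0.4}
    proximal: {count: 50, target_ks: 0.20, indel_rate: 0.0130, indel_length_p: 0.4}
    # transposed copies evolve under relaxed selection (omega near 1)
    transposed_recent: {count: 60, target_ks: 0.30, indel_rate: 0.0250, indel_length_p: 0.4, omega: 1.0}
    transposed_old: {count: 50, target_ks: 0.80, indel_rate: 0.0250, indel_length_p: 0.4, omega: 0.8}
  expression:
    n_samples: 20
    base_noise: 0.15
    noise_coupling: 0.15
  family:
    n_pairs: 15
    indel_multiplier: 3.0

classifier:
  max_evalue: 1.0e-10
  top_n: 5
  max_intervening: 10
  min_block_anchors: 5
  max_gap: 25
  recent_outgroups: [brassica, populus, vitis]
  broad_outgroups: [populus, vitis]

alignment:
  gap_open: 10.0
  gap_extend: 0.5
  matrix: BLOSUM62

alpha: 0.05
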