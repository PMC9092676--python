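# Reference study conditions: 20 risk loci, ~30 candidate genes per 2-Mb
# window, planted multi-omics signal at strength 10, a planted network
# module, a true causal effect of 0.5 for Mendelian randomization, and a
# 5-type single-cell design whose first cell type carries the risk genes
# as markers.  All values can be overridden per section.
seed: 42

simulation:
  n_chrom: 8
  n_genes: 1200
  n_loci: 20
  candidates_per_locus_target: 30
  effect_strength: 10.0
  module_edge_prob: 0.3
  background_edge_prob: 0.01
  theta_mr: 0.5
  n_instruments: 10
  n_cell_types: 5
  n_cells_per_type: 200

prioritize:
  restart_prob: 0.5
  threshold: 0.01
  burn_in: 500
  check_every: 100
  max_sweeps: 20000

mr:
  mr_p_threshold: 1.0e-4
  mr_r2_threshold: 0.001
  mr_window_bp: 10000000

csea:
  csea_zero_fraction: 0.95
  csea_top_fraction: 0.05
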