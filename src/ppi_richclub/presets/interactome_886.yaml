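# Synthetic preset at the scale of a curated disease interactome:
# 886 proteins, ~17,300 interactions (preferential attachment, m = 20),
# a 30-node planted rich-club core, hub-elevated literature frequencies
# and hub-biased drugs.
synthetic:
  n_nodes: 886
  degree_model: barabasi_albert
  ba_m: 20
  core_size: 30
  core_density: 0.8
  frequency_base: 20.0
  hub_fold: 4.0
  hub_quantile: 0.95
  n_drugs: 6
  targets_per_drug: 120
  hub_bias: 2.0
null_model:
  kind: degree_preserving
  n_networks: 1000
  swaps_per_edge: 10
richclub:
  core_threshold: 1.3
  plateau_threshold: 0.95
mcl:
  inflation: 2.0
  min_module_size: 5
enrichment:
  background_size: 20000
seed: 0
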