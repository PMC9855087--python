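# Quick-start pipeline configuration: small synthetic dataset, completes in
# well under two minutes on one CPU.
seed: 42
simulate:
  n_pathways: 2
  circuits_per_pathway: 2
  chain_length_range: [3, 4]
  n_samples: 150
  n_kdts: 20
  n_drivers: 3
  n_background_genes: 8
  driver_effect: strong
  noise_sd: 0.05
normalize:
  upper_quantile: 0.99
relevance:
  n_trees: 50
  max_depth: 6
  cv_folds: 5
  background_size: 20
selection:
  gamma: 1.0
stability:
  enabled: true
  M: 6
  subsample_fraction: 0.8
  bootstrap_reps: 200
  null_draws: 100
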