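# Demo pipeline config: small simulated nodule-field survey, full analysis.
simulate:
  n_areas: 2
  samples_per_stratum_per_area: 2
  n_specialist_otus_per_stratum: 6
  n_moderate_otus: 25
  n_generalist_otus: 6
  n_contaminant_otus: 3
  n_decoy_otus: 3
  depth_mean: 3000
  depth_sd: 300
  n_euk_otus: 25
  n_planted_pairs: 5
rarefaction_depth: 1000
permutations: 99
nmds:
  n_restarts: 2
  max_iter: 50
network:
  n_permutations: 99
seed: 11
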