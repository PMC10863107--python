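cohort:
  n_populations: 3
  individuals_per_population:
  - 3
  - 3
  - 3
  shared_site_pool_size:
  - 8
  - 8
  - 8
  private_site_rate: 3
  inheritance_probability: 0.5
  fragment_mean: 400
  fragment_sd: 80
  read_length: 500
  target_junction_depth: 200
  background_read_rate: 100.0
  min_separation: 2000
  seed: 11
calling:
  min_len: 100
  max_len: 1000
  min_depth: 100
  coverage_floor: 1
  blunt_tolerance: 10
  blunt_fraction: 0.5
  env_window: 1000
  merge_within_individual: 200
unify_tolerance: 200
proximity:
  promoter_window: 1000
  enhancer_window: 1000000
  promoter_oriented: true
overlay:
  cpm_min: 1.0
  min_sample_fraction: 0.25
  lfc_threshold: 1.0
  fdr_threshold: 0.05
  min_group_presence: 3
  n_permutations: 1000
  seed: 11
genome:
  chromosomes:
  - - chrA1
    - 3000000
  - - chrB1
    - 2000000
  env_loci:
  - - chrA1
    - 1200000
    - 1206000
    - +
  - - chrB1
    - 800000
    - 806000
    - '-'
genes_per_mbp: 12.0
n_expression_samples: 6
n_expression_genes: 60
prevalence_k: 10
outdir: demo_out
seed: 11
log_level: INFO
write_coverage: false
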