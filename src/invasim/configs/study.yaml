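# Study-design defaults: single-introduction invasion grid.
# 4 propagule sizes x 3 initial heterozygosities x 4 extinction rates,
# 20 replicates of 30 generations each.
base_seed: 42
output_dir: runs/study
survival_only: false

source:
  n_source: 10000
  n_loci: 5000
  frequency_mode: two-point
  burn_in_generations: 0
  mutation_rate: 5.0e-6

grid:
  propagule_sizes: [2, 10, 100, 1000]
  target_ho: [0.5, 0.3, 0.1]
  extinction_rates: [0.02, 0.05, 0.1, 0.2]

demography:
  fecundity_mean: 100
  carrying_capacity: 96000
  growth_mode: ceiling
  logistic_r: 1.0
  mutation_rate: 5.0e-6

n_replicates: 20
n_generations: 30
sex_balance: true
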