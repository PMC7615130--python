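inputs: {}
lisa:
  alpha: 0.05
  n_perm: 199
  variable: toilet_public
model:
  burn_in: 200
  n_chains: 2
  n_iter: 300
out_dir: run
predict:
  policy: marginal
  threshold: 0.8
  urban_only: true
predictors:
  buffer_km: 5.0
  predictor_list: null
  standardize: true
seed: 20100101
selection:
  burn_in: 100
  compare_random_effects: false
  fractions:
  - 0.05
  - 0.1
  n_chains: 1
  n_iter: 150
  reference: labels
simulate:
  eas_per_neighbourhood: 25
  margin_km: 6.0
  n_neighbourhoods: 4
  raster_resolution_m: 100.0
  seed: 20100101
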