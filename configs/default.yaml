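# Default full-scale experiment configuration.
# Every constant of the pipeline is pinned here; unknown keys are rejected.
seed: 0
biology:
  n_ages: 6
history:
  n_years: 40
  noise_sd: 0.3
  ssb_min: 30000.0
  ssb_max: 300000.0
  start_year: 1979
  true_form: env_ricker
sst:
  start_year: 2000
  noise_sd: 0.3
  ar_coef: 0.5
reference_points:
  f_msy: 0.28
  msy_b_trigger: 97800.0
projection:
  f_cap: 3.0
  fbar_age_min: 2
  fbar_age_max: 4
  collapse_fraction: 0.1
  start_year: 2030
  end_year: 2100
economics:
  cost_exponent: 1.2
  cost_scale: 100.0
  target_mean_profit: 50000000.0
  hindcast_mean_catch: 45000.0
experiment:
  n_schemes: 200
  n_policies: 100
  catch_min: 400.0
  catch_max: 200000.0
  rate_min: 0.0002
  rate_max: 0.30
analysis:
  n_bins: 25
  profit_convention: any_year
  gbr_n_estimators: 100
  gbr_learning_rate: 0.1
  gbr_max_depth: 3
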