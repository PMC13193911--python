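# Example run configuration: synthetic cohort with a strong protective
# dose effect, nested grouped cross-validation, and dose recommendation.
generator:
  n_patients: 150
  beta_dose: -0.8        # log-hazard per Gy; negative = protective
  baseline_scale: 0.005  # Weibull scale rescaled for the steeper dose slope
  seed: 17
hyperparameter_grid:
  - {n_trees: 200, max_depth: 4, min_samples_leaf: 5, min_samples_split: 10, max_features: 0.58, seed: 1}
k_outer: 5
k_inner: 3
tau: 18.0
horizons: [6, 12, 18]
dose_min_gy: 10.0
dose_max_gy: 18.0
dose_step_gy: 0.5
utility: lc_at_12m
tie_tol: 0.005
bootstrap_B: 30
permutation_repeats: 5
seed: 17
output_dir: gksurv_out
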