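# gksurv

Lesion-level local-control survival modelling and prescription-dose decision
support for Gamma Knife radiosurgery (GKRS) of recurrent glioblastoma.

## The problem

Outcomes after radiosurgery for recurrent glioblastoma are heterogeneous, and
prescription-dose selection must balance the local-control gain of dose
escalation against toxicity risk in previously irradiated brain.  `gksurv`
implements a two-model decision-support pipeline for this setting:

* **Model A — local-control survival model.**  A random survival forest for
  right-censored time to local failure of a treated target, built from
  treatment-time clinical (age, sex, KPS), tumor (contrast-enhancing volume,
  anatomic and tumor localization, molecular markers) and plan covariates
  (prescription dose, isodose line, maximum dose, coverage).  Trees split on
  the standardized two-group log-rank statistic and carry Nelson–Aalen
  cumulative hazards Ĥ(t) = Σ_{tᵢ≤t} dᵢ/nᵢ in their leaves; the ensemble
  prediction is S(t) = exp(−H̄(t)) and the risk score is the ensemble
  mortality Σₜ H̄(t).
* **Model B — dose recommendation engine.**  For one case, each candidate
  dose on a clinically feasible grid (default 10–18 Gy in 0.5 Gy steps) is
  injected into the record — the dose interactions `dose×volume` and
  `dose×KPS` recompute, and the maximum dose is rederived from the isodose
  identity max = prescription/(isodose/100) — and scored by predicted local
  control at 12 months (or expected local-control duration, the restricted
  mean ∫₀^τ S dt).  The recommended dose maximizes the utility, with ties
  within a configurable tolerance resolved toward the **lowest** dose.

Because lesions cluster within patients, every validation step is grouped at
the patient level: grouped K-fold cross-validation with inner-loop
hyperparameter tuning, fold-fitted preprocessing (training-median/mode
imputation, one-hot encoding, removal of all-missing predictors), censoring
distributions estimated on training folds only (Kaplan–Meier of the censoring
times, used for the IPCW Brier score), cluster bootstrap for confidence
intervals, and permutation importance by mean decrease in Harrell's C-index.

A synthetic cohort generator with a known Weibull proportional-hazards
dose–response (S(t|η) = exp(−(t/λ₀)^k·e^η), η linear in dose, volume, KPS and
MGMT status) is part of the package, calibrated to a published
recurrent-glioblastoma radiosurgery cohort (median age 60, KPS 80, volume
9.9 cm³, dose 14 Gy on 10–18, ≈25% local-failure events), so every stage is
testable end to end against ground truth.

## Worked example

With `examples/config.yaml` (a 150-patient synthetic cohort with a strong
protective dose effect, β_dose = −0.8 per Gy):

```bash
gksurv simulate --config examples/config.yaml
gksurv validate --config examples/config.yaml
gksurv recommend --config examples/config.yaml --case P0003:L1
```

prints

```
gksurv validation report (seed 17)
cohort: 174 lesions, 39 events
pooled C-index: 0.783  (folds: 0.947, 0.769, 0.747, 0.709, 0.745)
pooled IBS (tau=18m): 0.104
bootstrap 95% CI for held-out C-index: [0.741, 0.988] (cluster_bootstrap_percentile)
top predictors by mean decrease in C-index:
  dose_gy: +0.1958
  volume_cm3: +0.0176
  max_gy: +0.0068
  ...
```

and, for the selected case,

```
case P0003:L1: recommended dose 15 Gy (observed 15.5 Gy)
utility: lc_at_12m; 15 Gy chosen over the utility maximum (0.9417) within tie tolerance 0.005
  LC at 6 months: 0.949
  LC at 12 months: 0.941
  LC at 18 months: 0.902
  expected local control duration: 17.0 of 18 months
top contributors: dose_gy, volume_cm3, max_gy, age_years, isodose_pct
```

Reading: out-of-fold discrimination (pooled C-index 0.78) shows the forest
recovers the injected dose–response; the permutation ranking puts the dose
itself far ahead of every other predictor, as the generator dictates; and the
dose sweep for this case finds the 12-month local-control plateau beginning
at 15 Gy, recommending the lowest dose on it rather than the nominal utility
maximum — the explicit toxicity-sparing tie-break.  `dose_candidates.csv`
holds the full ranked candidate table and the recommended curve.

The same commands accept a real cohort file via `cohort_path` in the config;
the expected columns, units and category levels are documented in the shipped
`schema.json` (see `gksurv.cohort.load_schema_descriptor()`).

## What this is not

No causal dose–response claims (training data are observational; the engine
is decision support within observed practice ranges), no toxicity or
overall-survival endpoints, no imaging or plan-geometry processing.  See
`docs/methods.md` for the model, the generator, numerical conventions and
limitations.
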