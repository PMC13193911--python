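# Methods

## Data model

One row per treated radiosurgical target (`LesionRecord`): patient and lesion
identifiers, clinical covariates (age in years, sex, KPS on the 40–100 grid),
tumor covariates (contrast-enhancing volume in cm³, anatomic localization
coded 1–6, tumor localization coded 1–3), molecular fields (MGMT, EGFR, PTEN,
TERT, chromosome 7+/10−), plan covariates (prescription dose in Gy, isodose
line in %, maximum dose in Gy, coverage fraction), follow-up time in months
and a local-failure indicator.  Follow-up time and the event flag are
mandatory; rows with missing or non-positive time are rejected with their row
indices.  Every other covariate may be missing, and out-of-range or
unparseable entries (for example a KPS of 85, off the 10-point grid) are
coerced to missing with a logged warning rather than silently corrected.
Patients may contribute several targets; the patient is the unit of all
splitting and resampling.

## Preprocessing

Imputation and encoding parameters are fitted on training rows only and
stored in an `EncoderState`: numeric predictors receive the training median,
categoricals the training mode (imputation precedes encoding, so the mode
level absorbs missingness), and predictors without a single observed training
value are dropped.  Kept categoricals expand to one indicator per
non-reference level.  The reference convention mirrors the source coding of
each field: fully observed binaries and the two location codings drop one
reference level (F for sex, "no" for chromosome 7+/10−, level 1 for both
localizations), while molecular fields whose source coding carries an
explicit "not available" pseudo-level emit indicators for every substantive
level and the pseudo-level is never emitted as a column.  Two engineered
products, dose×volume and dose×KPS, are appended and recomputed at transform
time from the (possibly counterfactual) dose.  With the full default
predictor list the encoded matrix has exactly 28 columns: 9 numeric
(7 measured + 2 interactions) and 19 indicators.  Unseen levels at transform
time encode as all-zero indicators with a warning, keeping prediction total.

The EGFR coding retains all four source levels (ampl/unampl/mut/unmut) even
though they mix amplification and mutation vocabularies; the package
reproduces the source coding rather than reinterpreting it.

## Survival forest

Trees are grown on bootstrap samples (n draws with replacement).  At each
node ⌈max_features·p⌉ features are sampled without replacement; candidate
thresholds are midpoints of consecutive sorted unique values; the split
maximizes the standardized two-group log-rank statistic |O−E|/√V, with O the
observed left-group events over the node's event times, E and V the
hypergeometric moments.  Ties in the best statistic break toward the lowest
feature index, then the lowest threshold, so fitting is bit-reproducible
given the seed (per-tree RNG streams are spawned from a single seed
sequence).  Nodes stop splitting at the depth limit, below the minimum split
size, when no events remain, or when no admissible threshold respects the
minimum leaf size.  Degenerate configurations (one side empty, zero
variance) score zero.

Leaves store the Nelson–Aalen cumulative hazard of their bootstrap rows on
the shared grid of unique training event times.  The Nelson–Aalen estimator
(rather than Kaplan–Meier) is used so that ensemble aggregation is a plain
average on the hazard scale: S(t) = exp(−H̄(t)) is then guaranteed
non-increasing in [0,1].  The risk score is the ensemble mortality, the
averaged cumulative hazard summed over the grid; it is monotone under
pointwise stochastic ordering of the predicted curves.  Forests serialize to
JSON (grid, node arrays, leaf hazards, bootstrap indices) and reconstruct the
exact predictor.

The default tuning grid spans n_trees {200, 500}, max_depth {3, 5, none},
min_samples_leaf {3, 5, 10} (with min_samples_split twice the leaf size) and
max_features {0.33, 0.58, 1.0}.  The command-line pipeline defaults to a
three-configuration subset of that grid; tests and the acceptance script use
one- or two-configuration grids with 100–500 trees, sized so that a full
nested cross-validation completes in tens of seconds at a few hundred
lesions.

## Metrics

*Harrell's C-index*: a pair (i,j) is comparable iff tᵢ < tⱼ strictly and i
failed; tied event times are not comparable; tied risks earn half credit.
The implementation enumerates all pairs (cohorts here are small) and raises
on data without a single comparable pair.

*Censoring distribution*: Kaplan–Meier product-limit with the event
indicator flipped.  Step functions are right-continuous; the left limit
G(t⁻) needed by the weights is taken from the jump bookkeeping, never via an
epsilon shift.

*IPCW Brier score* at horizon t: failures by t contribute Ŝᵢ(t)²/G(Tᵢ⁻),
subjects observed beyond t contribute (1−Ŝᵢ(t))²/G(t), subjects censored by
t contribute zero; the sum is divided by n.  A vanishing weight raises a
named singularity error rather than returning an inflated score.  The
integrated Brier score averages BS(t) over [0,τ] by the trapezoid rule on
the unique observed times augmented with the endpoints; τ defaults to
18 months, the largest standard reporting horizon, and is configurable.

*Curve summaries*: local-control probability at fixed horizons uses the
previous-grid-value step convention (S ≡ 1 before the first event time, last
value carried forward), and expected local-control duration is the
restricted mean survival time computed exactly as a sum of rectangle areas —
forest curves are genuinely piecewise constant, so no quadrature is
involved.

## Validation design

Outer grouped K-fold (default 5) deals seeded-shuffled patients into
near-equal folds; inner grouped K-fold (default 3) on the outer-training
patients drives the grid search, selecting the configuration with the best
mean inner C-index (first grid entry wins ties).  Per outer fold the
encoder, the censoring distribution and the tuned hyperparameters are
functions of the training rows only; fold degeneracy (an outer-training
split without events) is detected for all folds up front.  Pooled estimates
are fold means.

Uncertainty comes from either patient-level cluster bootstrap (patients
resampled with replacement, lesions travelling together, relabelled so
repeated draws stay distinct clusters; percentile intervals; undefined
replicates dropped with a logged count) or repeated grouped CV across seeds;
both are implemented and the method is tagged in the output.  Percentile
rather than BCa intervals are used for simplicity.

Permutation importance permutes one encoded column at a time within the
held-out block (no refitting) and reports the mean decrease in C-index over
R repeats, averaged over folds; a constant column is reported as exactly
zero.

## Synthetic cohort generator

Covariate marginals are calibrated to the reference cohort: age truncated
normal (mean 61.8, sd 11.1, range 27–82); KPS categorical centred at 80
(median 80, mean ≈79); volume log-normal with median 9.9 cm³ (σ_log = 0.95)
clipped to [0.12, 48.4]; prescription dose normal (13.8, 1.5) rounded to the
half-Gy grid and clipped to [10, 18] (median 14); isodose normal (51.8, 7.7)
clipped to [38.8, 80.9]; maximum dose derived through the isodose identity;
coverage normal (0.96, 0.03) clipped to [0.8, 1]; sex 70% male; MGMT
methylated with probability 0.51; localization frequencies follow the
reference distribution.  By default 15% of patients carry two lesions, which
share all patient-level covariates.  Missingness is injected completely at
random per field, sparse for plan variables and heavy (35–50%) for molecular
fields, mirroring routine documentation practice; no informative-missingness
mechanism is modelled because none is documented.

Event times follow a Weibull proportional-hazards model,
T = λ₀·(−log U / e^η)^{1/k} with
η = β_dose·dose + β_vol·vol + β_kps·(KPS/10) + β_mgmt·1[methylated],
so S(t|η) = exp(−(t/λ₀)^k·e^η).  Negative β_dose is protective — the
direction the dose-recommendation problem presumes.  Censoring is the
minimum of an exponential time (rate 1/14 per month) and a 60-month
administrative horizon; the observed time is the exact minimum of the three
latent times.  Default hazard parameters (k = 1.3, λ₀ = 3.5 months,
β_dose = −0.18, β_vol = 0.045, β_kps = −0.12, β_mgmt = −0.5) were calibrated
once, by Monte-Carlo, to yield ≈25% failures within the horizon with a
median failure time near 9 months, matching the reference cohort's censoring
profile.

Two named scenarios fix the study conditions for testing:
`strong_signal_params` steepens the dose slope to −0.8 per Gy (λ₀ rescaled
to 0.005 to hold the event fraction; the true linear predictor attains a
C-index of ≈0.8, leaving headroom for a fitted model to demonstrate
recovery), and `null_dose_params` sets β_dose = 0 (λ₀ = 23.6), under which
any learned dose–response is noise.

What the generator does **not** emulate: interval censoring from scheduled
imaging (times are exact, whereas real failure times are bracketed between
scans), informative censoring, center effects, and correlation between dose
and tumor covariates induced by physician judgment (doses are assigned
independently of volume and location, so generator-based tests cannot expose
confounding-by-indication, which the real decision problem has).  Passing
tests therefore demonstrate algorithmic correctness and leakage resistance,
not clinical transportability.

## Dose engine conventions

Candidate grids are arithmetic sequences within the feasible range (default
10–18 Gy, 0.5 Gy steps).  Injection replaces the prescription dose, rederives
the maximum dose from the isodose identity, and holds coverage fixed — no
plan re-optimization is modelled; both policies are recorded in the case
report metadata.  Doses outside the feasible bounds are refused.  The default
utility is predicted local control at 12 months; expected local-control
duration over τ is the alternative.  The recommendation takes the lowest
dose whose utility is within `tie_tol` (default 0.005 on the probability
scale) of the grid maximum: the model optimizes predicted local control
only, and the tolerance makes the preference for sparing previously
irradiated brain explicit and auditable rather than hidden in the ranking.

A practical note on dose–response profiles: the mean utility-versus-dose
profile of a bagged ensemble carries finite-ensemble noise of order 10⁻³
per grid step even when the underlying effect is strictly monotone, and the
engineered dose×volume feature is ambiguous under counterfactual injection
(a high product can mean high dose or high volume).  Monotonicity of mean
profiles is therefore assessed at the engine's tie resolution — no step down
the grid may lose more than `tie_tol` — which is exactly the resolution at
which the recommendation logic treats utilities as distinct.

## Problem sizes and numerical choices

Study-scale checks use 200 generated patients (≈230 lesions) for
cross-validation experiments, 400 for the dose-engine profile study and 100
held-out cases per sweep; forests use 100–500 trees.  Null-calibration
estimates average three independent outcome permutations of one cohort,
because a single permutation of a clustered cohort this size retains
spurious covariate–outcome correlation of order 0.05 on the concordance
scale.  All RNG streams derive from explicit seeds (numpy `SeedSequence`
spawning per tree); repeated runs are byte-identical.

## Known limitations

Headline clinical-cohort metrics are not reproducible here because the
source data are unavailable; synthetic results characterize the machinery,
not the clinic.  The evaluation horizon for the integrated Brier score is a
convention (18 months) rather than a reported value.  The forest has no
out-of-bag machinery (validation is grouped CV throughout), no competing
risks, and no calibration-curve diagnostics.  The cluster bootstrap refits
with fixed hyperparameters for tractability; it does not propagate
tuning-selection uncertainty.
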