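# Methods

This note documents the statistical model behind `gliosurv`, the choices
made where the design was genuinely open, and what the synthetic cohorts do
and do not establish.

## Data model

A cohort is four aligned tables keyed by `patient_id`: clinical (age in
years; gender; extent of resection dichotomized as gross/near-total vs
partial/biopsy; MGMT status), a real-valued radiomic feature matrix whose
columns are tagged `conventional` or `deep` (image processing is upstream;
the matrix is consumed as given), a binary mutation matrix over a fixed
27-gene panel, and overall survival in months with every event observed.
The no-censoring contract is asserted at load time, not silently assumed:
it is what makes the Kaplan–Meier estimator collapse to the empirical
survival function and lets the Brier score use unit weights. Missing cells
are rejected rather than imputed. For regression, gender is coded female=1,
EOR gross/near-total=1, MGMT methylated=1, so protective effects appear as
hazard ratios below 1.

MGMT calling from the 4-CpG pyrosequencing assay: `methylated` iff both the
mean and the median percent methylation are ≥ 10%; `not_detected` iff both
fall below the 4.5% detection limit; everything else is `low_positive`. No
quantitative variability criterion exists for the "highly variable" flavour
of low-positive calls, so every detected-but-not-methylated sample is
low_positive. For modelling, the call is collapsed to methylated vs not
(low_positive counts as unmethylated by default).

## Stage 1: the radiomic survival-prediction index

Preprocessing. The mean-absolute-deviation filter runs on **raw** feature
values, before z-scoring, with default ε = 1e−8: after standardization
every column has unit scale, so a variation filter is only meaningful
beforehand, and filtering first avoids dividing by near-zero standard
deviations. Z-scoring statistics come from the discovery cohort only; the
replication cohort is transformed, never refit.

Classifiers. Both endpoints (OS < 6 months vs all; OS ≥ 18 months vs all)
use a linear-kernel maximum-margin classifier because recursive feature
elimination needs per-feature weights. Nested CV: 5 stratified external
folds estimate generalization; inside each external **training** portion,
5-fold internal CV drives RFE (≈10% of the initial feature count removed
per round, floor of 8 features, subset chosen by balanced accuracy) and the
regularization grid search (default 7 log-spaced values in [1e−3, 1e3]).
Internal folds subdivide the external training portion — the standard
construction — since tuning on the evaluation fold would invalidate it. The
external-fold model with the best plain validation accuracy is kept. Class
imbalance (the risk extremes are minorities) is handled by
inverse-frequency class weights.

Calibration. Platt's two-parameter sigmoid is fitted by maximum likelihood
on decision values pooled **out of fold** across the external splits;
resubstitution outputs would bias pseudo-probabilities toward 0/1. Targets
are smoothed to (N±+1)/(N±+2) so perfect separation yields a finite slope.
The high-risk pseudo-probability is converted to P(not high-risk) before
averaging, so both SPI inputs point toward longevity and higher SPI means
longer predicted survival. Note that only a *shared affine* increasing
recalibration of both pseudo-probabilities is guaranteed to preserve the
SPI ranking; separately warping the two components nonlinearly can reorder
sums.

The stopping rule that would fix the selected-feature count to any
particular value is deliberately not tuned; the RFE floor and step are the
only knobs, and the selected subsets vary across folds and seeds by design.

## Stage 2: genomic selection and layered integration

Penalized Cox. The L1 path is solved by the coordinate-descent elastic-net
solver (scikit-survival's coxnet, l1_ratio = 1). The λ grid is data
adaptive: 100 log-spaced values from λ_max (smallest penalty with empty
support) down to 0.01·λ_max. Within the nested protocol the grid is
computed **per outer repetition from the outer-training part only**, so
outer-test patients can never inform λ_min — permuting their survival
changes only the outer-test c-index. Cross-validated deviance is the
Verweij–van Houwelingen construction, −2·[ℓ_full(β̂₋k) − ℓ_train(β̂₋k)]
summed over folds, with the package's own Efron-tie partial likelihood.
Ties in "highest outer-test c-index" break toward the smaller λ_min
(deterministic, and inclusive of borderline genes). The final fit at
λ_final uses the full cohort; the selected genes then enter models 5–6 as
unpenalized binary indicators, since per-gene hazard ratios are part of the
deliverable.

Layered models. Six nested covariate sets (clinical; +MGMT; +SPI;
+MGMT+SPI; +MGMT+genes; all) are fit on the identical patient set by
maximum partial likelihood with Efron tie handling and Wald inference. Age
enters untransformed in years; SPI as a single continuous covariate in
[0, 1]. Survival curves use the Breslow baseline cumulative hazard. The
c-index CI is a patient-level percentile bootstrap (default 1000
resamples); the method behind published CIs is rarely stated, and the
bootstrap is assumption-light here. The in-sample c-index is the primary
report.

Evaluation. Harrell's c-index counts pairs with distinct event times;
tied risk scores contribute ½. The Brier score at t is the mean of
(1[T_i > t] − S_i(t))²; the IBS is its trapezoidal time-average over the
event-time grid restricted to [0, τ], with τ defaulting to the 95th
percentile of observed times — the tail of the integrand at the maximum
time is dominated by a single patient, and no integration horizon is
standard. IBS changes are reported as signed percentages against the
covariate-free Kaplan–Meier reference (negative = improvement).

Risk groups. Tertiles of the fitted linear predictor define low/medium/high
groups (cut quantiles configurable); the rule is rank-based, and boundary
ties go to the lower-risk group. Separation is the k-sample log-rank
statistic with hypergeometric variance; group curves carry Greenwood
log-log 95% bands.

## Synthetic cohorts

The generator emulates the statistical shape of a two-cohort GBM study:
404 discovery + 112 replication patients drawn from one process and split
disjointly; age ~ truncated N(64, 12²) on [20, 90]; P(female) = 0.40,
P(gross/near-total) = 0.60, P(methylated) = 0.375; 27 mutation covariates
with deterministic per-gene prevalences spread over [0.03, 0.40] and a
small causal subset (defaults: protective NOTCH2 −1.2 and RB1 −0.9,
mildly deleterious EGFR/MET/PDGFRA +0.3); a rank-5 latent factor model for
the features (features = Z·Λ + noise) in which the **factors**, not
individual columns, carry survival signal — mimicking correlated radiomic
blocks so that RFE-selected subsets may vary while the SPI signal stays
recoverable. Survival times are Weibull proportional hazards sampled by
inverse transform, S(t|η) = exp(−(t/b)^k e^η), so quantiles are available
in closed form for calibration oracles; the baseline scale defaults to the
value that puts the median at 12 months at the expected linear predictor
(with shape k = 1, b = 12/ln 2 ≈ 17.3 when all effects are zero). Times
are continuous by default; a month-rounding switch exists to exercise tie
handling. Default clinical effects: β_age = 0.03 per year, β_EOR = −0.8,
β_MGMT = −0.6, β_gender = 0 — magnitudes chosen to match hazard ratios
typical of GBM prognostic models (≈1.03/yr, ≈0.45, ≈0.55).

What the synthetic cohorts do **not** emulate: real radiomic marginal
distributions (only their correlation structure), co-occurrence and
mutual exclusivity patterns among mutations, dependence between clinical
covariates, or any imaging artefacts. Passing tests therefore demonstrate
that the pipeline recovers structure it is designed for under its own
model assumptions — not clinical performance on real patients.

## Problem sizes and numerics

Tests and the acceptance script run at reduced, stated sizes chosen as the
smallest that leave the checked effects comfortably identifiable: pipeline
replicates use 200 discovery / 112 replication patients, 64 feature
columns, a single SVM regularization value, 5×5 outer/inner LASSO
repetitions with a 50-value λ grid, and 100-resample bootstrap CIs;
parameter-recovery checks use n = 2000 (Cox coefficients), n = 5000
(calibration), and 20 replicates of n = 112 (gene selection, causal
prevalences 0.40/0.35 and coefficients ±0.7). The λ→0 penalized fit is
solved as a vanishing penalty (1e−9, solver tolerance 1e−9), matching the
unpenalized maximum-partial-likelihood fit to ≈1e−5 on well-conditioned
problems. Degenerate inputs fail loudly: all-tied times, single-class
labels, constant or collinear covariates, empty feature sets after
filtering.

## Known limitations

* The coxnet path solver uses Breslow tie handling internally while the
  package's own likelihood evaluations use Efron; with the default
  continuous synthetic times the two coincide.
* Monotone containment of LASSO supports along the λ path holds only up to
  coordinate-descent tolerance; tests check it on well-separated problems.
* The six-model comparison is non-monotone between models 4 and 5 in
  general (radiomic vs genomic layers are not ordered); only nested chains
  are expected to improve.
* With strong latent effects and omitted-covariate frailty, marginal
  coefficient estimates in misspecified submodels attenuate toward zero;
  recovery checks therefore plant signal only in modelled covariates.
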