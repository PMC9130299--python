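# gliosurv

Multi-omic overall-survival (OS) modelling and risk stratification for
IDH-wildtype glioblastoma, as a tested, reusable Python pipeline.

Glioblastoma prognosis varies widely with clinical factors (age, extent of
resection), molecular markers (*MGMT* promoter methylation, gene mutations)
and imaging phenotype. `gliosurv` implements a two-stage analysis that
quantifies how much each data layer adds to survival prediction:

**Stage 1 — radiomic survival-prediction index (SPI).** On a discovery
cohort, two linear SVM classifiers are trained on a high-dimensional
radiomic feature table (conventional + deep-feature columns, consumed as
given): `SVC_high_risk` separates short survivors (OS < 6 months) from all
others, and `SVC_low_risk` separates long survivors (OS ≥ 18 months) from
the rest. Training uses 5×5 nested cross-validation with recursive feature
elimination (features ranked by |SVM weight|); features are first passed
through a mean-absolute-deviation filter and z-scored with discovery
statistics only. Decision values are mapped to pseudo-probabilities by
Platt sigmoid calibration, p = 1/(1 + exp(A·d + B)), fitted on out-of-fold
decisions, and averaged after orienting both toward longevity:

    SPI = ( P(not high-risk) + P(low-risk) ) / 2  ∈ [0, 1]

Higher SPI predicts longer survival. The frozen model is then applied to an
unseen replication cohort.

**Stage 2 — layered Cox proportional-hazards integration.** On the
replication cohort, the 27-gene binary mutation matrix is first reduced by
a double-nested LASSO-Cox protocol (inner repeated 3-fold CV minimizes the
Verweij–van Houwelingen cross-validated deviance to pick λ_min; outer
random 75/37 splits score each λ_min by test-set concordance; the best
becomes λ_final, and a full-cohort LASSO fit at λ_final defines the
selected genes). Six nested Cox models are then fit by maximum partial
likelihood on the same patients:

| model | covariates |
|---|---|
| 1 | clinical (age, gender, EOR) |
| 2 | clinical + MGMT |
| 3 | clinical + SPI |
| 4 | clinical + MGMT + SPI |
| 5 | clinical + MGMT + selected genes |
| 6 | clinical + MGMT + SPI + selected genes |

Each model reports per-covariate hazard ratios with 95% CIs, Harrell's
c-index with a bootstrap CI, the integrated Brier score (IBS) of its
Breslow-baseline survival curves, and the signed IBS change versus a
covariate-free Kaplan–Meier reference. Predicted risk is cut at tertiles
into low/medium/high groups whose separation is tested by the k-sample
log-rank statistic. All estimators assume fully observed event times (no
censoring), which the loaders enforce.

Because the patient data behind such studies are not public, the package
ships a first-class synthetic cohort generator
(`gliosurv.simulate`) that plants recoverable survival structure — Weibull
proportional-hazards times, latent-factor radiomic signal, causal mutation
subsets — so every stage is testable end to end.

## Worked example

```python
from gliosurv.simulate import SyntheticConfig, generate_replication_split
from gliosurv.signature import train_signature, apply_signature
from gliosurv.genomics import NestedLassoConfig, select_lambda_nested
from gliosurv.integration import run_layered_models

cfg = SyntheticConfig(
    n_discovery=200, n_replication=112,
    n_conventional_features=24, n_deep_features=40,
    beta_latent=(1.0, -0.8, 0.6, 0.0, 0.0), seed=11,
)
disc, rep, truth = generate_replication_split(cfg)

model = train_signature(disc, c_grid=[1.0], seed=11)
spi = apply_signature(model, rep)

sel = select_lambda_nested(
    rep.mutations, rep.os_months.to_numpy(),
    NestedLassoConfig(n_outer_reps=5, inner_reps=5, n_lambdas=50, seed=11),
)
results, table = run_layered_models(rep, spi, sel.selected_genes, seed=11)
print(table[["model", "label", "c_index", "ibs", "ibs_reduction_pct"]]
      .round(3).to_string(index=False))
```

prints

```
 model                                  label  c_index   ibs  ibs_reduction_pct
     1                               Clinical    0.632 0.096             -6.648
     2                        Clinical + MGMT    0.652 0.092            -11.104
     3                   Clinical + Radiomics    0.723 0.089            -13.484
     4            Clinical + MGMT + Radiomics    0.736 0.084            -18.343
     5             Clinical + MGMT + Genomics    0.693 0.082            -20.260
     6 Clinical + MGMT + Radiomics + Genomics    0.779 0.082            -20.746
```

Reading the table: the clinical-only model discriminates weakly (c-index
0.63); adding the radiomic SPI lifts it to 0.72, and the full multi-omic
model reaches 0.78 with a 21% reduction in integrated prediction error
versus the Kaplan–Meier reference — each data layer adds information
because the generator planted independent signal in each.

The same pipeline is scriptable from the shell:

```bash
gliosurv run-all --seed 11 --out results/run11     # simulate → ... → stratify
gliosurv report --out results/run11
```

Every run writes a manifest (config hash, per-stage seeds, SHA-256 output
checksums); reruns with the same configuration and seed are bit-identical.

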