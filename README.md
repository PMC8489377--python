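# vancopk

Population pharmacokinetics of vancomycin in infants with normal and
augmented renal function: a one-compartment IV-infusion model, FOCE
mixed-effects estimation, renal-function-stratified covariate models,
stepwise covariate selection, and the standard pharmacometric
diagnostic/validation suite — together with a synthetic-cohort generator
that emulates the study population, so every stage can be exercised and
tested end to end.

## The problem

Vancomycin is cleared almost entirely by glomerular filtration, and
renal function varies enormously across infants: some present augmented
renal clearance (ARC, estimated GFR ≥ 86 ml/min/1.73 m²), others sit in
the infant-normal band of 30–86 ml/min/1.73 m². Pooled pediatric PK
models blur this distinction. This package implements a stratified
analysis: separate population models for the normal-renal-function
group, the ARC group, and the pooled population, built and validated
with the same machinery.

## The model

Concentrations follow a one-compartment model with zero-order infusion
input and first-order elimination (parameters CL in L/h and V in L,
k = CL/V). Between-subject variability is log-normal,
P_i = TV(P)·exp(η_i) with η ~ N(0, ω²) on CL, and residual error is
proportional, Y = F·(1 + ε) with ε ~ N(0, σ²) (additive and mixed forms
are also supported). Typical values carry allometric weight scaling and
a renal-function covariate:

    Model 1 (normal):  CL = θ₁·(WT/2.25)^θ₃·exp(θ₅·SCR/27.1),  V = θ₂·(WT/2.25)^θ₄
    Model 2 (ARC):     CL = θ₁·(WT/4.6)^θ₃,                    V = θ₂·(WT/4.6)^θ₄
    Model 3 (pooled):  CL = θ₁·(WT/3.45)^θ₃·exp(θ₅·SCR/19),    V = θ₂·(WT/3.45)^θ₄

with WT in kg and serum creatinine (SCR) in μmol/L. Renal function is
stratified by the modified Schwartz formula
eGFR = 88.4·k·HT/SCR (k = 0.33 preterm < 1 y, 0.45 term infants,
0.55 children). The published coefficient sets are available from a
built-in registry (`load_model_spec("model1"|"model2"|"model3")`).

Estimation is first-order conditional estimation with interaction
(FOCE-I): each subject's marginal likelihood is Laplace-approximated
about the conditional mode of η, the inner mode search is a vectorised
safeguarded Newton iteration across subjects, and the outer fit is a
quasi-Newton minimisation of the objective function value
(OFV = −2 log-likelihood) over (θ, ω², σ²). Covariate selection uses
stepwise forward addition (ΔOFV > 3.84, χ² df=1 α=0.05) and backward
exclusion (ΔOFV < 10.83, α=0.001); diagnostics include CWRES
goodness-of-fit tables, visual predictive checks, a nonparametric
bootstrap, and MPE/MAE/RMSE external validation with Wilcoxon paired
model comparison.

## Worked example

Simulate a 64-subject ARC cohort (40 mg/kg/day in 2–4 infusions,
trough/peak sampling around the fifth dose) from the published ARC
model, then re-estimate its parameters and bootstrap them:

```python
from vancopk import (CohortConfig, PopPKModel, PopulationParameters,
                     load_model_spec, simulate_dataset)

spec = load_model_spec("model2")
truth = PopulationParameters.published("model2")
cohort = simulate_dataset(CohortConfig(n_subjects=64, group="augmented", seed=7),
                          truth, spec)
result = PopPKModel(cohort, spec).fit(init=truth)
print(result.summary())
boot = result.bootstrap(n_reps=100, seed=7)
print(boot.table.round(3).to_string(index=False))
print(f"success rate: {boot.success_rate:.0f}%")
```

prints

```
Population PK fit (FOCE with interaction)
  model spec:     model2 (model-2)
  subjects/obs:   64/128
  OFV:            697.839
  converged:      True (14 iterations)

parameter  estimate
   theta1    0.7704
   theta2     5.037
   theta3     1.175
   theta4     1.059
   BSV_CL    0.3352
  PROP_RV    0.2568

  eta-shrinkage (CL):  4.4%
  eps-shrinkage:       21.2%

parameter  estimate  median  p2.5  p97.5  bias_pct
   theta1     0.770   0.769 0.689  0.840    -0.174
   theta2     5.037   5.013 4.587  5.476    -0.474
   theta3     1.175   1.157 0.934  1.397    -1.493
   theta4     1.059   1.080 0.863  1.319     2.038
   BSV_CL     0.335   0.325 0.233  0.396    -3.183
  PROP_RV     0.257   0.250 0.214  0.305    -2.778
success rate: 100%
```

The recovered typical clearance (θ₁ ≈ 0.77 L/h at the 4.6-kg median
weight) and volume (θ₂ ≈ 5.0 L) sit close to the generating values
(0.756 L/h, 4.89 L); every bootstrap bias is within a few percent of
the point estimate and the percentile intervals bracket it, which is
what a stable, identifiable fit of this design looks like. Shrinkage of
the empirical Bayes η estimates is low, so individual-level diagnostics
are trustworthy.

A `vancopk` command-line pipeline (`simulate`, `fit`, `select`, `vpc`,
`bootstrap`, `validate`) wraps the same library calls; each subcommand
reads a YAML config and writes its outputs plus a reproducibility
manifest into a run directory.

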