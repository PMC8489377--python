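# Methods

## Structural and statistical model

Drug amount in a single well-stirred compartment obeys
dA/dt = rate_in(t) − (CL/V)·A, with rate_in the sum of active zero-order
infusion rates. The closed-form solution for one infusion (rise
(R₀/CL)(1 − e^(−k·t)) during the infusion, exponential decay after) is
superposed over all doses; no steady-state shortcut is taken because the
TDM design anchors sampling to the fifth dose, not to steady state.
Units are fixed package-wide: hours, mg, L, mg/L (numerically identical
to μg/ml). A Runge–Kutta integration of the mass balance, segmented at
the rate discontinuities, serves as an independent oracle and agrees
with the closed form to 1e−6 relative on randomized regimens.

Between-subject variability is exponential, P_i = TV(P)·e^η with
η ~ N(0, ω²). The three final models carry BSV on CL only; the engine
also supports a second η on V (diagonal Ω) for base-model exploration.
Residual error may be additive, proportional, or mixed; the final
models use the proportional form, whose SD scales with the prediction.

Typical values follow the allometric-plus-renal-covariate vocabulary
described in the README. Two deliberate conventions:

* The serum-creatinine factor is the exponential `exp(θ₅·SCR/median)`
  exactly as the models are parameterised — it is *not* unity at the
  median, so typical CL at median creatinine includes the factor
  `exp(θ₅)`. This preserves fidelity to the estimable form.
* Maturation form III's factor is the increasing sigmoid
  Age^Hill/(TM50^Hill + Age^Hill), which satisfies MF(TM50) = 0.5 and
  rises to 1 with age; ages inside maturation functions are in years
  (data columns carry months). Forms IV/V make the allometric exponent
  itself a declining sigmoid in weight or age.

Renal stratification uses the modified Schwartz eGFR with
k ∈ {0.33, 0.45, 0.55}. The study population spans 1–24 months, where
the published k classes leave 12–23 months unassigned; the package uses
the term-infant k = 0.45 up to 24 months and 0.55 from 2 years. The
eGFR axis is partitioned as [30, 86) → normal, ≥ 86 → augmented
(the boundary belongs to ARC), < 30 → excluded.

## Estimation

The marginal −2 log-likelihood is approximated per subject by a Laplace
expansion about the conditional mode η̂ (FOCE with interaction: the
residual variance is evaluated at the conditional prediction, which
matters for the proportional error model):

OFV = Σ_i [ h_i(η̂_i) − d·log 2π + log det(H_i/2) ],
h_i(η) = −2 log p(y_i|η) − 2 log p(η).

* **Inner step.** A vectorised safeguarded Newton iteration solves all
  subjects' 1-D (or 2-D) mode searches simultaneously: central finite
  differences (step 1e−4), per-subject backtracking on h, gradient
  tolerance 1e−8 scaled by (1+|h|), with a coarse-grid initialisation
  (±4 prior SDs, 17 points) on cold starts and a grid-restarted retry
  for any straggler. With ω = 0 the objective degenerates exactly to
  the fixed-effects −2 log-likelihood.
* **Outer step.** L-BFGS-B over transformed parameters: log transforms
  enforce positivity of the structural coefficients θ₁/θ₂ and of all
  variance components (reported as SDs, used internally as variances);
  exponents and covariate coefficients are unconstrained. Tolerances:
  relative f-tolerance 1e−10, gradient 1e−6, forward-difference step
  1e−6, 300 iterations. Variance-component SDs are floored at 1e−3 so a
  near-interpolating fit cannot drive the conditional problem into an
  ill-posed spike. A line search that cannot improve an initial value
  already at the optimum is reported by the optimizer as abnormal
  termination; a finite, non-increased OFV still counts as converged.
* **Initialisation.** Refits and simulation studies start from the
  published estimates jittered ±20% multiplicatively; de-novo fits use
  a crude TDM heuristic (per-subject CL from daily dose over 24× the
  trough/peak mean, V from a typical infant k of 0.15 h⁻¹).
* **Oracles.** An adaptive Gauss–Hermite quadrature (≥ 32 nodes,
  centred and scaled at the conditional mode) and a vectorised
  Monte-Carlo marginal likelihood provide independent references; the
  Laplace OFV tracks quadrature within one unit on the small problems
  where quadrature is exact enough to judge.

Estimation is deterministic given data and initial values; all
randomness lives in data simulation. OFV *differences* drive every
downstream decision; the additive constant (full Gaussian densities,
including 2π terms) is fixed so differences are comparable across
models on the same data.

Empirical-Bayes diagnostics: η-shrinkage = 100·(1 − SD(η̂)/ω) and
ε-shrinkage = 100·(1 − SD(IWRES)), IWRES = (Y − IPRED)/sd(IPRED), both
with sample SDs; ω = 0 makes η-shrinkage undefined (NaN). CWRES uses
the conditional linearisation: per subject, the residual y − (f(η̂) −
G·η̂) is decorrelated by the Cholesky factor of G·Ω·Gᵀ + diag(var(f(η̂)))
with G = ∂f/∂η at η̂; a singular covariance falls back to IWRES with a
warning.

## Covariate selection

Selection is a pure function of OFVs and thresholds, driven by an
oracle callable so the same engine replays a recorded OFV table or the
live estimator. Forward addition admits the largest OFV drop per round
if it exceeds the χ²(df=1) quantile at α = 0.05 (3.84); when several
candidates pass, best-drop-first is used. Backward exclusion iterates
one removal per round — the cheapest — while the rise stays below the
α = 0.001 quantile (10.83); the structural weight allometry is
removable only when explicitly listed. An oracle failure on a candidate
skips that candidate with a warning, never a silent admission or
removal. Maturation screening picks the smallest OFV with ties broken
by fewer estimated parameters, then listed order. Candidates enter
clearance only; weight scales both CL and V. Continuous covariates
enter as centered power terms, serum creatinine and binary flags as
exponential factors — the final models' functional vocabulary.

## Synthetic cohorts

The generator emulates the modeling groups' printed summaries, which
are the package's study conditions:

* Weight and creatinine are log-normal, matched to the group medians
  (normal: WT 2.25 kg, SCR 27.1 μmol/L; ARC: WT 4.6 kg, SCR
  16.8 μmol/L), truncated to the printed ranges; log-SDs (0.40/0.42 for
  WT, 0.30/0.25 for SCR) were chosen once to span those ranges with
  realistic right skew. Height follows weight through HT ∝ WT^0.29
  (passing through the group medians) with 5% log-normal noise. Age has
  a 60% point mass at 1 month (the printed median) plus a truncated
  geometric tail to 24 months; preterm status, sex and co-medication
  are Bernoulli at the printed group frequencies. Auxiliary labs are
  independent log-normals around the group medians and exist only to
  exercise covariate screening.
* Group membership is enforced by recomputing eGFR and resampling
  SCR/height until the classification matches (bounded rejections).
  A useful side effect: creatinine values incompatible with the
  eGFR ≥ 30 inclusion bound cannot occur.
* Dosing: 40 mg/kg/day read as a *total* daily dose (the printed daily
  doses at the median weight are ≈ 44 mg/kg/day, contradicting a
  per-dose reading), split evenly into 2–4 one-hour infusions at q12/q8/q6
  intervals, six doses generated. Dose amounts divide exactly; no mg
  rounding is applied.
* Sampling: one trough 30 min before the fifth dose and one peak 30 min
  after the end of the fifth infusion (the standard vancomycin TDM
  anchor; the alternative "30 min after infusion start" reading would
  sample inside the infusion).
* The mixed (whole-population) group draws each subject from the normal
  profile with probability 61/115, otherwise from the ARC profile.

What the generator does *not* emulate: time-varying renal function
(each synthetic subject belongs to one group; the study's
double-counted "fluctuating" patients have no analogue), correlation
among auxiliary labs, dose adjustments after TDM, disease types, and
co-medication effects on PK. Passing tests therefore demonstrate that
the estimator and diagnostics behave correctly under the assumed
generative model at the study's design and scale — not that the
published coefficients are correct for real infants.

## Problem sizes and stabilised summaries

Simulation studies run at the study scale: 64 ARC and 61
normal-renal-function subjects per cohort, 115 for the pooled design,
10 replicate simulate-and-refit experiments for parameter recovery, 100
bootstrap resamples (the published analysis used 1000), 100–800 VPC
replicates. Two reported summaries are medians over replicate
experiments rather than single draws, because they are extreme or
ratio statistics with heavy Monte-Carlo tails at this scale: the
worst-parameter bootstrap bias (per-parameter biases medianed over five
independent cohort+bootstrap experiments, then maximised) and the
η-/ε-shrinkage of the pooled design (median over five replicate
cohorts). The replication counts reduce variance only; they do not
alter the generating conditions, thresholds or seeds.

## Degenerate inputs and edge policies

Empty dose lists predict zero; observations before the first dose are
permitted (zero prediction, infinite proportional-error contribution is
reported rather than masked). Negative simulated observations are
statistically legitimate under the error model, left in place, counted
and logged (< 1% at the published σ). Bootstrap replicates that fail to
converge count as failures, are excluded from percentiles and lower the
reported success rate. Dataset validation collects every violation with
row numbers in one pass. The Wilcoxon comparison of two external
validations pairs absolute individual prediction errors per
observation; an all-zero difference vector is reported as "identical"
rather than tested. External-validation forecasting conditions each
subject's MAP η on all of that subject's observations jointly.

## Known limitations

One-compartment kinetics only (no two-compartment or nonlinear
elimination); no interoccasion variability, SAEM or full-Bayes
estimation; standard errors come from a finite-difference Hessian and
are optional; the quadrature oracle covers 1-D η only; real-data
external validation is out of reach without the original concentrations,
so validation here is against synthetic cohorts from the published
models.
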