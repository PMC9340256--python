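# Methods

## Structural and statistical model

Escitalopram disposition is modeled as one compartment with first-order
absorption and elimination in apparent parameterization (CL/F, V/F;
bioavailability F is not separately identifiable from oral TDM data).
For a dose D at time 0,

C(t) = (1000·D/V) · k_a/(k_a − k_e) · (e^(−k_e t) − e^(−k_a t)),
k_e = CL/V,

with doses in mg, volumes in L, times in h and concentrations in ng/ml;
the single factor 1000 converts mg/L to ng/ml and is applied exactly
once, inside this kernel. Multiple dosing is linear superposition;
steady-state troughs use the geometric-series closed form (equivalence
to ≥20-half-life superposition is asserted in the test suite to
<0.1%). The removable singularity k_a = k_e is evaluated by its
analytic limit when |k_a − k_e| < 10⁻⁹·k_a.

Between-subject variability is log-normal on CL/F and V/F. Residual
error is proportional (additive component fixed to 0; the assay's
working range makes a proportional model adequate). Covariates act
multiplicatively on clearance:

* CYP2C19 phenotype, from the diplotype over {\*1, \*2, \*3}:
  \*1/\*1 → EM (reference), \*1/\*2 and \*1/\*3 → IM, \*2/\*2 and
  \*2/\*3 → PM, with free multipliers θ_IM and θ_PM;
* age, linear: 1 − θ_age·(age − 45). The positive sign of θ_age
  encodes clearance *decreasing* with age (a `age_sign` switch flips
  the convention). The centering age is 45 y, the study cohort's
  median, so the typical clearance refers to the same reference
  subject as the published estimates; centering is a
  reparameterization and does not change model fit.

Linear calibrators can go non-positive at extreme covariate values;
multipliers are clamped at a floor of 0.05 with a logged warning rather
than raising, because synthetic cohorts may sample extremes.

Defaults of `PopulationParameters` are the final published estimates:
TVCL 16.3 L/h, TVV 815 L, k_a 0.6 h⁻¹ (fixed, literature value —
trough-dominated sampling carries no absorption information),
θ_age 0.0077 y⁻¹, θ_IM 0.847, θ_PM 0.479, ω²_CL 0.0877, ω²_V 0.235,
σ²_prop 0.0287.

## Estimation: FOCE-I

The marginal likelihood has no closed form. Per subject, the penalized
deviance

pen(η) = Σ_j [(y_j − f_j(η))²/v_j(η) + log v_j(η)] + ηᵀΩ⁻¹η,
v_j(η) = σ²_prop f_j(η)² + σ²_add,

is minimized over η (the empirical-Bayes estimate; the residual
variance follows the conditional prediction — the "interaction" in
FOCE-I; a config flag freezes it at the η = 0 prediction for plain
FOCE). The subject's objective contribution is the conditional
approximation

OFV_i = Σ_j [log(2π v_j) + (y_j − f_j)²/v_j] + log|Ω| + η̂ᵀΩ⁻¹η̂
        + log|H_i/2|,

where H_i is the **first-order (Gauss–Newton) curvature** of the
penalized deviance at η̂ — the linearization FOCE performs. This keeps
the objective exactly equal to the closed-form marginal −2 log L for
models linear in η with additive error, and smooth in the population
parameters (the exact η-Hessian can cross positive/negative
definiteness as parameters move, which makes the outer objective
discontinuous). All 2π constants are included, so absolute OFVs differ
from NONMEM's constant-free convention by n_obs·log 2π while OFV
*differences* — the quantity used for covariate testing — are
identical.

Numerics that matter:

* The inner problem is solved for all subjects simultaneously with a
  vectorized Levenberg–Marquardt iteration using analytic first- and
  second-order sensitivities of the concentration kernel; gradient
  tolerance 10⁻⁸, with per-subject adaptive damping (a backtracking
  Newton line search stalls in the curved likelihood valleys that
  sparse trough designs produce). Stragglers are handed to a subsetted
  engine and, if needed, a derivative-free rescue; unconverged
  subjects are flagged.
* The inner solve always starts from the same data-driven point
  (η_CL matching the subject's mean observed level), never from the
  previous outer iterate: sparse subjects can have several conditional
  modes, and history-dependent warm starts make the outer objective
  non-deterministic, which corrupts ΔOFV comparisons.
* Fixed effects and variances are optimized on the log scale;
  covariate calibrators on the natural scale, internally rescaled by
  the covariate spread for conditioning. The outer optimizer is
  L-BFGS-B (forward-difference gradients, step 10⁻⁶) with an automatic
  restart on abnormal termination; convergence is declared when the
  optimizer succeeds or a restart no longer improves the OFV by 0.05.
* Standard errors (optional covariance step) come from the central
  finite-difference Hessian of the OFV, cov = 2H⁻¹, delta-method
  mapped to the natural scale.
* Observations below the assay lower limit of quantification
  (3 ng/ml) are excluded from fitting with a logged count; a censored
  (M3-type) likelihood is out of scope.

## Covariate selection

Stepwise forward inclusion / backward elimination on OFV differences
with the study's thresholds: include when ΔOFV > 6.63 (χ², 1 df,
p < 0.01), retain when removal raises the OFV by ≥ 10.83 (p < 0.001).
The CYP2C19 phenotype is tested as one 2-df block (both multipliers
together), matching its joint definition. Ties break lexicographically
by candidate name, making the search deterministic. Candidate fits are
warm-started from the incumbent model's estimates with a null new
effect; every step is logged (candidate, ΔOFV, df, decision) and the
log replays to the final model. Generic continuous candidates center
at the dataset median; missing weight/height are imputed to the
population median before search.

## Validation battery

* **Bootstrap**: subjects resampled with replacement to the original
  count (no stratification), each replicate refitted; medians and
  percentile 2.5/97.5% bounds over converged replicates; failures
  counted, not fatal.
* **CWRES**: first-order expansion about η̂; E = f(η̂) − Gη̂,
  COV = GΩGᵀ + diag(v(η̂)), CWRES = L⁻¹(y − E) with L the lower
  Cholesky factor (jittered if singular, logged). Approximately
  standard normal under a correct model. Note the lower-triangular
  decorrelation depends on within-subject observation order; only
  cross-subject invariance is a true model property.
* **NPDE**: n_sim model simulations on the original design; per
  subject, observed and simulated vectors are decorrelated by the
  empirical mean and Cholesky factor of the simulated covariance; the
  pde is the rank among simulations with a 1/(2·n_sim) continuity
  correction (extremes clipped), mapped through Φ⁻¹. The battery is a
  t-test (mean 0), a two-sided χ² dispersion test (variance 1) and
  Shapiro–Wilk (normality); the global p is Bonferroni (3 × min p).
  Default n_sim 1000, reduced in desk-scale tests.
* **Goodness of fit**: per-observation table of DV, PRED (η = 0),
  IPRED (η̂), CWRES and time after last dose — the table behind the
  standard diagnostic plots.

## Synthetic cohorts

The generator reproduces the study design so estimation, selection and
validation are testable without the (undeposited) patient data:

* 106 subjects; CYP2C19 diplotype frequencies \*1/\*1 0.4434,
  \*1/\*2 0.4528, \*1/\*3 0.0094, \*2/\*2 0.0660, \*2/\*3 0.0284
  (implying EM 44.3% / IM 46.2% / PM 9.4%); 55.66% male.
* Ages from an equal-probability mixture of U(12, 45) and U(45, 83):
  median exactly 45 and range 12–83 as published. The study reports
  only location and range; this mixture's dispersion (sd ≈ 20 y) also
  reproduces the magnitude of the age-covariate likelihood-ratio
  statistics the study reports, which a mode-peaked (triangular)
  sampler understates by about half.
* Regimens drawn from the six reported dosing schemes (5–20 mg qd,
  5–15 mg bid; daily dose 5–30 mg, median 10 mg), dosed daily for 21
  days.
* Sampling is trough-dominated: observation count per subject is
  1 + Poisson(mean ≈ 2.2) targeting ~337 total; times uniform in the
  last 2 h of a dosing interval after at least 5 intervals, with a 10%
  admixture of random post-dose times that gives mild volume
  identifiability (the study notes most samples were near trough but
  includes non-steady-state samples).
* Concentrations from the structural model at η ~ N(0, Ω) with
  proportional noise; records below 3 ng/ml flagged BLQ. Laboratory
  covariates (ALT, m-AST, TBIL, ALB, urea, creatinine), weight, height
  and sex are generated with **no** kinetic effect — null decoys for
  selection-specificity experiments. Dose assignment is independent of
  phenotype (no titration rule is reported).

What passing tests on these cohorts do **not** show: robustness to
model misspecification (the generator uses the fitted model family),
dose titration feedback, adherence gaps, or assay artifacts — real TDM
data contain all four.

## Dose-regimen simulation

Steady-state troughs by closed form (superposition equivalence is
oracle-tested) for 5/10/15/20 mg daily regimens across EM/IM/PM and
representative ages 16 (adolescent), 45 (adult median), 65 (elderly),
classified against the AGNP window: <15 / [15, 80] / (80, 160) / ≥160
ng/ml, boundary values inclusive in the therapeutic and alert bands.
Population simulations sample η per virtual subject; residual (assay)
error is excluded by default — troughs represent biological exposure —
with a flag to include it for predictive intervals. Both
typical-subject values and population percentile bands are emitted.

## Desk-scale experiment sizes

The validation experiments in the test suite run at reduced but
design-faithful sizes chosen once: NPDE self-consistency at 20 seeds ×
200 simulations; covariate selection at 20 seeds × 106 subjects with
two null decoys (sex, weight) and selection-grade optimizer precision
(gtol 5·10⁻³); replicate parameter recovery at 5 × 80-subject cohorts;
the null inclusion-rate check at 40 × 10-subject cohorts with an upper
bound allowing Monte-Carlo error. The acceptance script fits one full
106-subject study from a neutral start.

## Known limitations

* Conditional (FOCE-I) estimation carries the method's usual
  small-sample biases with 3 observations per subject; recovered
  typical clearances average a few percent above the generating value
  across seeds, comfortably inside the published bootstrap interval.
* V/F and ω²_V are weakly identified by trough-only designs (the
  published relative standard errors show the same); recovery
  intervals for them are wide.
* BLQ records are excluded rather than modeled; at the study's
  concentration range this affects ~1% of records.
* The inner conditional problem can be multimodal for very sparse
  subjects; the deterministic start makes basin choice reproducible,
  and competing basins differ by ≪1 OFV unit, but an exhaustive global
  inner search is not attempted.
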