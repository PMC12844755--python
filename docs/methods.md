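# Methods

## Structural and covariate model

Teicoplanin concentrations are described by a one-compartment model with
first-order elimination and zero-order infusion input, parameterized in
clearance `CL` (L/h) and volume `V` (L). Concentration-time curves for any
multiple-infusion schedule are evaluated from the closed-form
single-infusion solution by superposition (`pk_core.concentration`):
during an infusion of rate `R0 = amount/duration`, a dose contributes
`(R0/CL)(1 − e^{−ke s})`; afterwards the end-of-infusion value decays as
`e^{−ke (s − dur)}`, with `ke = CL/V` and `s` the time since the dose
started. The solution is exact (no ODE solver), nonnegative, additive over
doses and linear in the amounts — properties the test suite asserts to
machine precision. The steady-state pre-dose concentration of a periodic
schedule has the usual accumulation closed form
(`pk_core.steady_state_trough`); tests verify it against long-horizon
superposition after ≥10 half-lives.

Clearance carries three covariates, normalized to the development cohort's
medians: a power of eGFR (reference 92.15 mL/min), a power of Devine ideal
body weight (reference 61 kg) and a centered linear age term (reference
62 y). Defaults are the final published estimates (CLpop 1.28 L/h, Vpop
92.10 L, exponents 0.35 and 3.2, age slope 0.012 /y). Two printed-source
choices deserve note: the Devine formula is implemented with division by
2.54 (cm→inch), which reproduces the cohort's median IBW of 61.4 kg at
165 cm male — the alternative subtraction reading gives physiologically
absurd weights; and the age slope defaults to the equation value 0.012
(the parameter table's 0.01 is a rounding of the same quantity; the choice
is irrelevant at the reference age and configurable). eGFR is consumed as
a plain number in mL/min with no body-surface de-indexing. A non-positive
age term raises an error rather than clamping: a silent clamp would hide
extrapolation abuse.

Between-subject variability is log-normal on CL and V with diagonal Ω
(the analysis reports only the two variances, so no covariance is
estimated); residual error is purely additive, the structure selected for
trough-only data in which proportional components are poorly identifiable.
IIV is reported as CV% using the `100·ω` convention common in PopPK
tables; the exact log-normal transform `100·sqrt(exp(ω²)−1)` is available
alongside (the difference is <2 points at ω ≈ 0.34).

## Estimation

`estimation.fit_model` maximizes a per-subject Laplace approximation of
the marginal likelihood, expanded about the conditional mode η̂ of the
random effects with Gauss–Newton curvature `G'G/σ² + Ω⁻¹` (G = ∂f/∂η at
η̂). With additive error the residual variance does not depend on η, so
this objective coincides with FOCE with interaction; the OFV includes all
constants, making it a drop-in −2 log-likelihood for χ² model comparison.
The Ω → 0 limit is handled exactly by writing the curvature term as
`log det(I + (G'G/σ²)Ω)` and pinning η components with zero variance.
Tests pin the objective against adaptive numerical integration on tiny
instances (agreement within 0.1) and against a closed-form Gaussian
constant in the degenerate one-observation case.

The inner η-search is a dense Levenberg–Marquardt on the stacked residual
`[(y − f(η))/σ ; η/ω]`, hand-rolled because the problem is 1–2 dimensional
and sits in the innermost loop; it is started both at zero and at the
previous outer iteration's mode (tie-break by lower objective) and warm
starts are cached across outer iterations. The outer optimizer is L-BFGS-B
on a transformed scale: log for CLpop, Vpop, σ and the ω²; identity for
power exponents; linear/categorical coefficients are rescaled by the
largest centered covariate value and boxed inside the region where every
subject's covariate factor stays positive — this both conditions the
search and keeps the optimizer away from the domain boundary of the age
term. Estimates within 1e-3 of an optimizer box set a boundary flag, which
the bootstrap uses as its discard rule. Default tolerances: outer
projected-gradient 1e-3, inner gradient 1e-10; initial values are
literature-scale (CL 1 L/h, V 80 L, exponents 0.75/1/0, ω 0.3, σ 3 mg/L)
unless supplied. Observations below the 3.0 mg/L LLOQ are excluded before
fitting (the analysis' stated handling), not censored-likelihood imputed.

Standard errors come from a central finite-difference Hessian of the OFV
at the optimum (via `statsmodels.tools.numdiff`); the covariance is twice
the inverse Hessian on the estimation scale, delta-method transformed back
(RSE of a log-parameter is 100·SE of its log). η-shrinkage is
`100·(1 − SD(η̂)/ω)`, undefined at ω = 0.

## Covariate selection

Screening regresses empirical Bayes η̂ on each continuous candidate (OLS;
retained at p < 0.05 and r² > 0.10) and uses one-way ANOVA with an
explained-variance analogue for categorical candidates. The stepwise
search then works on the mixed-effects OFV: forward inclusion of the
largest drop while ΔOFV > 3.84, backward elimination of any effect whose
removal costs < 6.63. Power and linear forms are normalized to the
dataset median, recomputed per dataset and recorded on the effect; forward
ties within 0.01 OFV units break by screening r² so runs are
deterministic. Time-varying covariates follow a latest-record-at-or-before
carry-forward rule; predictions at an observation use the covariate values
in force at that time (an approximation to piecewise-varying parameters
that is exact for the constant-covariate datasets the generator produces).

## Qualification

CWRES uses the FOCE linearization: `y ≈ N(f(η̂) − Gη̂, GΩG' + σ²I)`,
whitened by the Cholesky factor of the covariance; at Ω = 0 it collapses
to `(y − f)/σ`. Under the true model its empirical mean carries a small
negative offset (≈ −0.07 at this design) from linearizing a log-normally
skewed model — within the ±0.1 band the tests assert and typical of
FOCE-based diagnostics. The nonparametric bootstrap resamples subjects
with replacement to the original cohort size, refits, discards
non-converged or boundary-flagged replicates, and reports medians with
percentile 95% CIs. The pcVPC follows the prediction-correction recipe:
each observed and simulated value is scaled by (bin median population
prediction / own population prediction), with equal-count time bins
(default 6; bins under 5 observations merge with a neighbor) and 95%
envelopes of each simulated percentile. External validation reports
MPE (bias) and MAPE (precision) of population (η = 0) predictions —
a priori performance; a MAP-conditioned variant is available.

## Simulation, nomogram, MAP dosing

`simulation.simulate_population` draws η ~ N(0, Ω) around the
covariate-predicted typical parameters and evaluates profiles on a
regular grid (default 14 days, past steady state). Target attainment is
computed on model concentrations without residual error: assay noise is
not exposure. The 72-h PTA uses the concentration at t = 72 h, which is
pre-dose for every study regimen under the maintenance-timing convention
(first maintenance dose one maintenance interval after the last loading
dose, so the 5×q12h loading phase hands over exactly at 72 h); the
steady-state PTA uses the analytic trough, asserted in tests to agree
with long-horizon simulation. Weight-based doses use total body weight by
default with an IBW option; simulation strata defined only by IBW set
total weight equal to IBW so the distinction vanishes there. Strata above
the cohort's 77 kg IBW support are flagged as extrapolation.

The nomogram exploits dose-linearity of steady-state troughs: the minimum
dose per (IBW, eGFR) cell is the smallest 50-mg multiple meeting the
target, exact without search, in typical-individual mode by default (one
dose per covariate cell, as a dosing chart prints); a PTA ≥ 90% mode
shares η draws across cells so the grid stays monotone. MAP-Bayesian
individualization reuses the conditional-mode machinery with population
parameters fixed; with no observations it returns the covariate-predicted
typical parameters (prior mode).

## Synthetic cohorts

The generator emulates the development study: sex ~ Bernoulli(0.40
female); heights from sex-specific truncated normals (male 172±7, female
160±6 cm) bounded so Devine IBW stays in [46.25, 77] kg; age truncated
normal on [18, 85]; eGFR a truncated log-normal on [26, 141] mL/min;
albumin truncated normal with a mild negative age correlation (the
cohort's age–albumin collinearity). For age and eGFR the location is
solved numerically so the *truncated* median equals the cohort median
(62 y, 92.15 mL/min) — naive placement undershoots after truncation.
Dosing follows the clinical protocol (600 mg q12h ×3, then once-daily
maintenance), sampling starts at 24 h and recurs at uniform 72–96 h gaps
snapped to the dosing grid, always immediately pre-dose. Follow-up is a
per-subject uniform 2–9 days, chosen so cohorts average ≈1.7–1.9 samples
per subject — the study's observation density (168 concentrations in 100
patients). TDM is emulated by scaling subsequent maintenance doses by
clamp(15 / measured trough, 0.5, 2), rounded to 100 mg — an invented,
logged simplification of clinical adjustment. The adjustment deliberately
uses the *measured* (noisy) value: adjusting on the latent noise-free
concentration would make dose assignment depend on the random effects
directly and confound likelihood estimation, whereas measurement-driven
adjustment is ignorable, as in real TDM practice.

What the generator does not emulate: diagnosis mix and inflammatory
markers as model-relevant variables (carried only as inert columns),
time-varying renal function, the validation cohort's slight distributional
shifts, and the clinical heterogeneity behind the study's per-patient
dose ranges. Passing recovery tests therefore show the estimator is
correct and well calibrated *for this design*, not that the published
model is correct for new patient populations.

## Problem sizes used in the tests

The test suite exercises every statistical claim at sizes chosen to keep a
full run at a few minutes of CPU while retaining power: the parameter
recovery and the acceptance pipeline use the full study dimensions (100
subjects, ~180 troughs, 1000 virtual subjects for PTA); calibration and
type-I-error properties run at reduced replicate counts (8–10 null
replicates for the ΔOFV > 3.84 inclusion rate, 8–12 bootstrap replicates,
200–300 VPC simulations) with binomial bounds set so a correct
implementation fails with probability ≲1%. Oracle comparisons (adaptive
quadrature, grid searches, brute-force dose scans) run on one- and
two-subject instances where the oracle is exact.

## Calibration of the recovery experiment, and known limitations

With the study's sparse trough-only design (~1.8 samples/subject),
maximum likelihood itself — not the Laplace approximation, which was
checked against 15×15-node adaptive Gauss–Hermite quadrature and tilts
slightly the other way — carries finite-sample bias: across replicate
synthetic cohorts the refits center near CLpop 1.31, Vpop 88, IIV-CL
30 CV%, σ 2.4, IBW exponent 2.9 (generating values 1.28 / 92.1 / 34.1 /
2.61 / 3.2). Variance components are ML- rather than REML-estimated, so
their downward bias is expected; single replicates can land outside the
published bootstrap intervals for CLpop or Vpop at unlucky seeds. Other
limitations: diagonal Ω only; additive error only (proportional/combined
structures are out of scope, having been rejected for this data type);
no censored-likelihood BLQ handling; one-compartment structure (the
richer-sampling alternative was rejected for this design); simulation
strata beyond IBW 77 kg rely on extrapolation and are flagged as such.
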