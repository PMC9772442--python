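# Methods

## The model

`venpk` implements a joint population-pharmacokinetic (popPK) model for an
orally dosed parent drug and its major metabolite — venlafaxine (VEN) and
O-desmethylvenlafaxine (ODV) — with first-pass (pre-systemic) conversion.
Three compartments carry amounts in mg of the labelled hydrochloride dose:

    dA0/dt = -ka * A0                                  (depot)
    dA1/dt = (1 - fp) * ka * A0 - kp * A1              (parent, central)
    dA2/dt =      fp  * ka * A0 + kp * A1 - km * A2    (metabolite, central)

with `kp = CL/F / V/F` and `km = CLm/F / Vm/F`. Concentrations are
`1000 * A1 / V/F` and `1000 * A2 / Vm/F` in ng/ml.

Two structural commitments deserve emphasis:

* **All systemic parent elimination is conversion to metabolite** (`kp`
  doubles as the parent-to-metabolite rate constant). After oral dosing
  with metabolite data only, the formed fraction is not identifiable; the
  standard resolution is to fold it — together with the parent/metabolite
  molar-mass ratio — into apparent metabolite parameters `CLm/F` and
  `Vm/F`. This choice also reproduces the parent's terminal half-life
  `ln 2 * V/CL = ln 2 * 628/80.9 = 5.4 h` from the final estimates.
* **One-compartment disposition for both analytes.** Two- and
  three-compartment models describe intravenous data better, but the data
  this analysis targets are dominated by sparse troughs that cannot
  support peripheral compartments.

Everything is linear, so doses superpose; a steady-state regimen
accumulates each exponential term by `1/(1 - exp(-lambda*tau))`. The
closed forms are evaluated with `expm1`-stable divided differences near
the `ka = kp` degeneracy (single doses use the exact L'Hôpital limit
`t * ka * exp(-ka t)`; coincident rates elsewhere are separated by a
relative 1e-8 nudge, a measure-zero configuration in practice). An
adaptive-ODE evaluation (`amounts_ode`, LSODA at rtol 1e-10) serves as the
in-package oracle; closed form and ODE agree to 1e-6 relative down to
concentrations of 1e-6 ng/ml, far below any assay limit (beyond that the
integrator's absolute tolerance, not the closed form, is the bottleneck).

Typical parameter values for the defaults are the published final-model
estimates: CL/F 80.9 L/h, V/F 628 L, CLm/F 22.1 L/h, Vm/F 238 L, Ka 0.63
1/h (fixed during estimation), Fp 0.048.

## Statistical model and FOCEI

Inter-individual variability is log-normal per parameter,
`P_i = P_tv * exp(eta_i)`, with a diagonal Omega on (CL/F, V/F, CLm/F,
Vm/F); the residual model is proportional per analyte,
`y = f * (1 + eps)` (an additive component is configurable but off by
default). The published variability values are read as variances
(omega^2: 0.219/0.106/0.156/1.38; sigma^2: 0.123 VEN / 0.101 ODV) despite
the "%CV" table heading — the variance reading is what NONMEM
conventionally reports, and it is internally consistent: with
omega^2_CL = 0.219 and 24 intensively sampled healthy subjects the
design-based SE of log CL is sqrt(0.219/24) = 9.6%, matching the
published 9.7% RSE.

Estimation is first-order conditional with interaction (FOCEI):

* per subject, the empirical-Bayes mode minimises
  `sum_j [(y_j - f_j)^2 / h_j + ln h_j] + eta' Omega^-1 eta` with
  `h = sigma^2 f(eta)^2` evaluated at the conditional estimate;
* with `G = df/deta` at the mode, `C = G Omega G' + diag(h)` and
  `r = y - f + G eta`, the subject's objective contribution is
  `ln|C| + r' C^-1 r` (the `n ln 2pi` constant is omitted, as in
  NONMEM-style OFVs).

On one-random-effect test problems this linearised OFV stays within 0.5
units of a 64-node adaptive Gauss-Hermite quadrature of the exact marginal
likelihood.

A consequence of the interaction term worth knowing: when observations sit
exactly at the typical predictions the eta mode is *not* exactly zero —
the `ln h(eta)` term tilts it by O(sigma^2). The tilt vanishes as
sigma^2 goes to 0, which is what the tests assert.

### Numerics

The inner (eta-mode) problem is solved for all subjects at once with a
two-phase damped Newton scheme: a positive-definite Gauss-Newton phase
(curvature at zero residual) for global progress, then an exact-curvature
phase — exact d2(loss)/df2 plus `J_a J_b / f` for the f-curvature, exact
for log-linear f — whose quadratic terminal convergence makes the modes
path-independent to ~1e-4 OFV units. Steps are capped at one unit of eta
per iteration with per-subject Levenberg damping and backtracking;
without the cap, subjects whose tail predictions underflow (slow
eliminators with late samples) produce astronomically overshooting raw
Newton steps.

The outer problem optimises transformed parameters (log for positive
quantities, logit for Fp, log(1+theta) for categorical covariate
coefficients) with L-BFGS-B. The objective *and its entire
forward-difference gradient* are evaluated in one vectorised pass by
tiling the design into p+1 virtual subject blocks, one per perturbed
parameter vector; eta modes are warm-started between evaluations. The
final reported OFV of every fit is re-evaluated cold (eta from zero) at
full inner precision, so ΔOFV comparisons between fits are deterministic.
A `fast_inner` option relaxes the inner tolerance during the outer search
only; it leaves threshold decisions unaffected because those use the
final cold OFVs.

Standard errors come from the inverse of half the central-difference OFV
Hessian, computed in the transformed coordinates with 0.02 steps (large
enough to dominate the objective's ~1e-4 noise floor) and mapped back by
the delta method; RSE% = 100 SE/|estimate|, with fixed parameters
reported as not applicable. A marginally indefinite Hessian (flat ridge,
see below) is repaired by eigenvalue clipping and flagged; a substantially
indefinite one falls back to a case-resampling bootstrap over subjects.

### Identifiability: the Fp ridge

With metabolite data only from steady-state troughs, Fp is close to
unidentifiable: at steady state essentially the whole absorbed dose
reaches the metabolite regardless of the first-pass split, so only the
intensive parent data constrain `CL/F / (1 - Fp)`. The likelihood surface
therefore has a flat ridge along (Fp, CL/F, Vm/F, omega^2_Vm): refits of
the same simulated dataset from different starting points end at
essentially equal OFV (within ~0.5 units) but with CL/F anywhere in
roughly a ±10% band and Fp between 0.04 and 0.14. This shows up honestly
in the Hessian-based uncertainties (RSE of Fp in the hundreds of
percent). Fits are therefore initialised at the published values — the
normal literature-informed choice in a re-analysis — and recovery checks
use ±3 simulation SEs, which is exactly the band the ridge inflates.

## Covariate machinery

Categorical covariates act as `TV * (1 + theta * X)` with signed theta (a
printed "61.7% decrease" is theta = -0.617); continuous covariates as
`TV * (X/ref)^theta` with the pooled median as reference. Stepwise
selection follows the published thresholds exactly: forward inclusion
accepts the candidate with the largest OFV drop strictly greater than
6.63 (p < 0.01, df 1), repeated to exhaustion; afterwards each retained
relation is removed one at a time from the full model and kept only if
removal raises the OFV by more than 10.83 (p < 0.001). Ties break
lexicographically on (parameter, covariate) for reproducibility. Health
status is not tested on metabolite parameters (the healthy study has no
metabolite observations, so such an effect is confounded with the
parameter's own typical value).

### Power of the selection experiment

A design-based calculation says the amisulpride effects are marginal at
the published thresholds under the default generator conditions: with 7
amisulpride patients out of 127 and omega^2_CL = 0.219, the
log-scale SE of the CL effect is ~0.18, the effect is ln(0.608) = -0.50,
so the noncentrality is ~7.5 — forward inclusion (>6.63) succeeds in
roughly 60% of replicates and backward retention (>10.83) in under 30%.
Twenty-seed runs at full patient count confirm it (observed amisulpride
ΔOFV between 3.5 and 10.6, including a forward acceptance later removed at
backward). The exact-final-model selection rate is therefore low by
design, not by implementation; the morbid-state effect, with
noncentrality ~40, is selected essentially always, and null covariates
are included at well under the nominal 1% forward rate. The packaged
selection experiment runs 20 seeds of a reduced design (6 healthy + 64
patients, four candidate relations) to keep the suite fast; the power
arithmetic above is scale-adjusted accordingly.

## Diagnostics

`gof_table` reports PRED (typical, covariate-adjusted, eta = 0), IPRED
(at the eta mode) and CWRES, the FOCEI-linearised residuals decorrelated
by the symmetric inverse square root of `C`. With Omega = 0 and a purely
proportional error model CWRES reduces exactly to `(y - f)/(sigma f)`.

`npde` simulates K full-population replicates under the model (new etas
and epsilons; design, doses and covariates fixed), decorrelates each
subject's observed and simulated vectors with the inverse Cholesky factor
of the empirical simulation covariance (both analytes stacked in one
vector; singular covariances are shrunk toward the diagonal with a
warning), takes the rank fraction of the observation among its replicates
and maps it through the standard-normal quantile. Rank fractions of 0 or
1 are clamped to `1/(2K)` and `1 - 1/(2K)`. K defaults to 1000 with a
floor of 100. Being rank-based after a linear decorrelation, npde is
exactly invariant to per-analyte unit changes. On model-true synthetic
data the npde sample is standard normal (mean within ±0.1, variance in
[0.8, 1.2]) and Shapiro normality rejects at roughly the nominal 5% rate.

## The synthetic studies

The generator emulates the two source designs:

* **Study 1** — 24 healthy male volunteers, two crossover periods 7 days
  apart, 50 mg orally, 15 scheduled parent samples per period (pre-dose,
  0.5-36 h), parent assay 0.2-200 ng/ml with the phase-dependent
  below-limit rule (zeroed in the absorption phase, excluded in the
  elimination phase; the absorption phase ends at the observed
  per-interval peak). Ages are uniform integers 18-27; weights normal
  (62.5, 6.9) truncated to [54, 80] kg.
* **Study 2** — 127 psychiatric patients at steady state, 2-4 morning
  trough visits each (sampled up to 1 h before the scheduled dose, on
  days 3-30), daily doses normal (132.9, 64.2) truncated to [25, 300] mg
  and rounded to 12.5 mg steps, given once daily (sustained release,
  83.6%) or split twice daily; quantitation ranges 4-400 (VEN) and
  20-2000 (ODV) ng/ml with out-of-range exclusion. Binary covariates
  follow the published frequencies — female 55.1%, smoking 7.9%, drinking
  4.7%, valproate 18.2%, quetiapine 23.4%, clozapine 15.7%, olanzapine
  24.5%, risperidone 13.2%, amisulpride 5.5% — assigned as exact rounded
  counts by default (a Bernoulli mode exists); laboratory covariates
  (ALT/AST/BUN/CR) are generated from the published moments but carry no
  true effect, existing to exercise null-covariate behaviour.

True parameters default to the published final model, including the three
covariate effects (morbid -> CL/F -0.617; amisulpride -> CL/F -0.392 and
-> CLm/F +0.593). The generator emits a truth record (all parameters plus
every subject's etas) for recovery testing.

What the generator does *not* emulate: assay error beyond proportional
noise, missed doses and adherence gaps, titration before steady state,
inter-occasion variability, CYP2D6/CYP2C19 phenotype strata, and the
specific below-limit pattern of the real intensive study (so the real
study's retained-observation count of 664 is approximated by the design
count of 720 minus whatever the rules censor, typically 30-80 samples).
Passing recovery and calibration tests on these data therefore shows the
estimator and diagnostics are correct *under the stated model*, not that
the model captures every feature of real TDM data.

Crossover periods are treated as independent occasions with complete
washout: in the estimation design each observation is attributed only to
its own period's dose event. The period-2 pre-dose sample then has a
structurally zero prediction; structurally zero observations are
uninformative under a proportional error model (their likelihood is
degenerate) and are dropped from the likelihood, with the count recorded
on the fit result. The generator still simulates true carryover (it is
physically present, merely ~5 half-lives decayed), so rare slow-eliminator
subjects can show a measurable period-2 pre-dose concentration; ignoring
that tail during estimation mirrors the washout assumption of the original
analysis.

## Problem sizes used in the packaged checks

The recovery experiment simulates and refits the full 151-subject pooled
design once (seed 978202 in the test suite; the acceptance script takes
the seed from the command line). The selection-consistency experiment
uses 20 seeds of the reduced design described above; npde calibration
uses 20 seeds of a 40-patient trough design at K = 1000; the
approximation-oracle checks use 10 single-subject problems (quadrature)
and 100 random parameter draws (ODE). Unit tests run smaller replicates
of the same machinery.

## Known limitations

* The Fp/CL ridge means point recovery of CL/F from one replicate of this
  design is only determined to ~±10% even with a perfect estimator.
* Omega is diagonal; no inter-occasion variability; proportional-only
  error by default ("mixture" residual behaviour reported for the real
  data is approximated by the proportional model, with the combined
  additive option left configurable).
* The FOCEI linearisation degrades for very sparse subjects with large
  omega^2 (the usual caveat); the quadrature comparison quantifies it for
  one-eta problems only.
* Below-limit handling follows the source rules (zero or exclude), not a
  censored-likelihood (M3-style) treatment; the elimination-phase
  exclusions bias the terminal phase slightly high, as the original
  analysis itself notes.
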