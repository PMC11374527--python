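# Methods

## Structural and statistical model

Vedolizumab serum kinetics are described by a two-compartment model with
zero-order infusion input and first-order elimination, parameterized as
(CL, V_c, Q, V_p).  Within any interval where the infusion rate and the
individual parameters are constant, the compartment amounts follow a linear
two-state ODE whose solution is written in closed form with the 2×2 matrix
exponential (macro rate constants λ₁ ≥ λ₂ > 0); the repeated-eigenvalue
case is handled by the analytic limit branch, triggered when the relative
eigenvalue gap falls below 1e-10.  A subject's timeline is cut at every
dose start, infusion end and covariate-change knot, and amounts are carried
across the cuts.  When a volume changes between segments the amounts are
rescaled by the volume ratio so that *concentrations* are continuous: a
piecewise-constant volume stands in for a smoothly drifting one, and an
instantaneous dilution step would be an artifact of the discretization.
Within segments the solution is exact to machine precision; unit bookkeeping
(mg amounts, L volumes, day times) makes concentrations come out directly
in μg/mL.

A parallel saturable elimination pathway (Vmax, Km) is available for model
comparison; it is integrated numerically (segment-wise LSODA, rtol 1e-10)
and reduces to the linear model at Vmax = 0.  Vmax carries mg/day units so
that the elimination flux Vmax·C/(Km+C) is dimensionally consistent with
mg amounts.

Individual parameters at reference covariates (weight 75 kg, albumin
4 g/dL, age 53 y, lymphocytes 0.1 K/μL, no GvHD) equal the published
typical values CL 0.148 L/day, V_c 3.12 L, Q 0.500 L/day, V_p 3.95 L.
Continuous covariates act as normalized power laws; the weight exponents on
Q and V_p are fixed allometrically at 0.75 and 1; GvHD involvement per site
(liver/skin/intestine) is an on-off multiplicative factor on CL.  The
published analysis does not print the estimated covariate coefficients, so
the defaults used as simulation truth are chosen to reproduce the reported
covariate effect sizes (clearance changing by roughly −20% to +30% between
the extreme observed weight/albumin percentiles): wt_on_cl = 0.5,
wt_on_vc = 0.6, alb_on_cl = −1.3, age_on_cl = −0.2, lym_on_cl = 0, all
GvHD factors 1.0.  All are configurable.

Random effects: η ~ MVN(0, Ω) with a full 3×3 block on (CL, V_c, V_p) on
the log scale; an inter-occasion effect κ ~ N(0, ω²_IOV) multiplies CL and
is redrawn at each dosing occasion.  A new occasion starts at a dose that
is followed by at least one observation before the next dose; dose
intervals without observations inherit the previous κ level rather than
adding an unidentifiable dimension.  Residual error is proportional
(optionally plus additive).  The default variance components are the
published ones: Ω = [[0.0827, 0.0214, −0.0253], [·, 0.0323, 0.0272],
[·, ·, 0.179]], ω²_IOV = 0.0315, σ²_prop = 0.0241.

## Estimation (FOCE-I)

Per subject, the joint random-effect vector ψ = (η, κ₁..κ_m) is set to the
mode of its conditional density (the inner problem), found by a damped
chord Gauss–Newton: the prediction Jacobian F (forward differences,
h = 1e-5) is frozen across a few accepted steps and refreshed on stall or
every third step, the gradient keeps the interaction terms from the
residual-variance dependence on ψ, steps are capped at 4 log units, and
iteration stops when the Newton decrement falls below 1e-9·(1+|g|).
Dimensions with zero prior variance are pinned at 0, which yields the
naive-pooled objective in the Ω → 0 limit.  With r = y − f(ψ̂) + F ψ̂ and
residual variances v evaluated at the conditional predictions (the
"interaction"), the subject's contribution is

    −2ll = n log 2π + log|V| + rᵀ V⁻¹ r,   V = diag(v) + F Ω F′.

The outer problem minimizes the total over an unconstrained scale: log for
positive parameters, log-Cholesky for Ω.  L-BFGS-B drives it with an
explicit forward-difference gradient in which every perturbed evaluation
restarts the inner problems from one snapshot of the conditional modes;
this cancels warm-start hysteresis, which would otherwise inject ~1e-2
noise into the objective differences and stall the line search.  The
covariance of estimates is 2 H⁻¹ from a central finite-difference Hessian
at the optimum (snapshot-started as well), mapped to the reporting scale by
the delta method.  Reporting follows the source conventions: log-scale 95%
CIs for positive structural parameters (whose printed intervals are
asymmetric), symmetric ±1.96 SE intervals for variance components,
CV% = 100·sqrt(exp(ω²)−1) for log-normal variability and 100·sqrt(σ²) for
the proportional residual, and shrinkage 100·(1 − SD(EBE)/ω) on the SD
scale.  AIC = OFV + 2·(number of estimated parameters); model comparison
treats |ΔAIC| < 2 as a tie resolved toward fewer parameters.

The objective is an FOCE-class approximation, not a bit-for-bit NONMEM
reproduction; its accuracy is checked against a numerical-quadrature exact
marginal on a one-observation problem (agreement to < 0.05 in −2ll units
across variance settings, with exact convergence to the fixed-effects-only
value as ω² → 0).

## Synthetic trials

The generator emulates the two source designs.  Phase 1b (n = 24): 75 mg
(3 subjects) or 300 mg doses at study days −1/+13/+42 with rich sampling
(pre-dose and 0.5/2/12/24 h on dosing days; 14 single-sample visits).
Phase 3 (n = 169): 300 mg at days −1/+13/+41/+69/+97/+125/+153 with
pre-dose trough and end-of-infusion samples per dosing day plus day +180
and an end-of-treatment visit.  Time zero is the first dose; a calendar
day d maps to t = d + 1 days.

Covariate distributions reproduce the reported population: 57% male;
age truncated-normal mean 50.8 (SD 12, range 18–72); baseline weight
log-normal solved by least squares from the reported 51/75/105 kg
percentiles; baseline albumin N(3.97, 0.49) g/dL; baseline lymphocytes
log-normal with mean 0.426 K/μL (log-SD 0.85); GvHD any-time incidences
3.1% liver / 32.1% skin / 8.8% intestine with truncated-exponential onset
(scale 30 d) after transplant, absorbing flags.  Weight follows a random
walk (SD 1 kg per 14-day step); albumin shows a transient post-transplant
dip (default amplitude 5% at day +7, recovered by day +60) plus
measurement noise — the amplitude is set so the observed albumin
percentiles match the reported ones (25th 3.6, 90th 4.6 g/dL); a deeper
dip would thicken the lower tail beyond them.  30% of phase-3 subjects
discontinue dosing after a uniformly drawn dose but still contribute the
late follow-up samples; these long post-dose tails are what produces the
sparse below-quantification (BLQ) records (~0.3% of observations, late
times only), matching the handful reported.  BLQ records are flagged and
excluded from fitting (M1).

Concentrations are generated through the same compiled event-table
representation the estimator uses — covariates step at data rows, κ at
dose rows — so a simulated dataset is exactly consistent with the model
read back from it.  This is deliberate: parameter-recovery and diagnostic
calibration then test the estimator, not the covariate discretization.
Real data differ in ways the generator does not emulate: covariates drift
between sampling times, assay error is not exactly proportional-normal,
dosing and sampling times carry recording error, and model misspecification
is never zero.  Passing tests therefore demonstrate internal correctness
and calibration of the machinery, not that the published estimates are
recoverable from real patients.

## Diagnostics

pcVPC: observations are binned by time after the most recent dose
(quantile bins, default 8; bins under 3 observations merge leftward), each
value is prediction-corrected by (bin median population prediction)/(own
population prediction), and the observed 5th/50th/95th percentiles are
compared with their 95% confidence bands across Monte Carlo replicates
(default 500) of the study.  NPDE: per subject, simulated replicate
vectors (default 1000) give a mean and covariance; observed and simulated
vectors are decorrelated by the inverse Cholesky factor
(ridge-regularized with a warning if singular), ranks use the mid-rank
rule pd = (k+0.5)/(n_rep+1), and npde = Φ⁻¹(pd), which is N(0,1) under
the true model.  Goodness-of-fit tables provide PRED (η = 0), IPRED (at
the EBE mode), residuals and EBE-vs-covariate joins including any-time
GvHD flags.

## Covariate forest inference

Uncertainty draws of (log CL_ref, covariate coefficients) come from a
multivariate normal on the estimation scale (so CL stays positive) using
the fit's covariance; per draw, CL with one covariate perturbed to an
observed percentile (5/10/25/50/75/90/95th, computed over observation
rows) and all others at reference is normalized by the reference CL (the
median draw at reference covariates).  Rows report the median and a 90%
interval by default (95% is available; the source describes both widths in
different places, without a clear canonical choice).  A ±25% band around
the reference marks the conventional clinical-relevance zone; rows whose
interval excludes it are flagged potentially important.  Relative
steady-state exposure is the reciprocal of relative CL (linear
elimination).  Under the default coefficients the extreme weight and
albumin rows land at roughly 0.79/1.24 and 1.36/0.84 — the most
influential covariates, consistent with the reported ≈20%/≈30% effect
sizes — while age and lymphocyte rows stay well inside the band.

## Problem sizes and numerical defaults

The parameter-recovery experiment simulates ~120 subjects (100 sparse
phase-3-style, 20 rich phase-1b-style) per replicate and 5 replicates,
fitting 16 parameters (4 structural, 4 covariate exponents, 6 Ω Cholesky
entries, IOV, residual) from inits perturbed ±30%; the lymphocyte and
GvHD coefficients — null in the generating model — are fixed rather than
estimated, keeping the refit at a size one CPU handles in a few minutes
per replicate.  Diagnostic calibration uses the full 193-subject design.
Outer convergence: L-BFGS-B ftol 1e-8, projected-gradient tolerance 0.5
(the objective is a ~1e4-magnitude sum; looser than machine precision by
design), maxiter 60 in the experiment.  Known limitations: no M3 BLQ
likelihood, no SAEM/importance sampling, no CWRES, covariance step may be
skipped on singular Hessians (CIs then suppressed), and the FOCE
linearization shares the general small-data biases of the method class.
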