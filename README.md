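# vedopk

Population pharmacokinetics of intravenous vedolizumab given for acute
graft-versus-host disease (aGvHD) prophylaxis in adults undergoing
allogeneic hematopoietic stem cell transplantation (allo-HSCT).

The package is aimed at pharmacometricians who want a self-contained,
testable re-implementation of this analysis: a nonlinear mixed-effects
(NLME) model of vedolizumab disposition, an FOCE-I estimator, a synthetic
generator for the two source trial designs, simulation-based diagnostics,
and covariate forest-plot inference.

## The model

Disposition is a two-compartment model with zero-order (30-min infusion)
input and linear elimination, parameterized as clearance CL, central volume
V_c, intercompartmental clearance Q and peripheral volume V_p.  Individual
parameters combine typical values at a reference patient (75 kg, albumin
4 g/dL, 53 years, lymphocytes 0.1 K/uL, no GvHD) with power-law covariate
effects and log-normal random effects:

    CL_i = 0.148 (WT/75)^θ_wt (ALB/4)^θ_alb (AGE/53)^θ_age (LYM/0.1)^θ_lym
                 × f_liver^I × f_skin^I × f_gut^I × exp(η_CL + κ_occ)
    Vc_i = 3.12 (WT/75)^θ_wt,Vc exp(η_Vc)
    Q_i  = 0.500 (WT/75)^0.75          (fixed allometric exponent)
    Vp_i = 3.95 (WT/75)^1 exp(η_Vp)    (fixed allometric exponent)

η ~ MVN(0, Ω) with a full 3×3 block on (CL, V_c, V_p), κ is an
inter-occasion effect on CL redrawn at each dosing occasion, and residual
error is proportional, y = f(1 + ε).  Weight, albumin, lymphocyte count and
aGvHD involvement are time-varying covariates (next observation carried
backward); concentrations below the 0.2 μg/mL quantification limit are
excluded before fitting (M1).  Estimation is by first-order conditional
estimation with interaction (FOCE-I): per subject the conditional mode of
(η, κ) is found by damped Gauss–Newton, the model is linearized there, and
the resulting Gaussian marginal gives the −2 log-likelihood.

## Worked example

```python
import numpy as np
from vedopk import (ModelParams, PopulationSpec, generate_population,
                    simulate_trial, apply_exclusions, fit)
from vedopk.estimate import format_report

truth = ModelParams()                      # the published final model
pop = generate_population(PopulationSpec(n_vedo_1015=10, n_vedo_3035=40), seed=1)
dataset, log = apply_exclusions(simulate_trial(pop, truth, seed=2))
print(f"{log.n_retained} observations retained "
      f"({100 * log.blq_fraction:.1f}% BLQ excluded)")

from vedopk.experiments import perturb_params
init = perturb_params(truth, np.random.default_rng(3))
result = fit(dataset, init, compute_covariance=False)
print(format_report(result))
```

prints (abridged):

```
782 observations retained (0.3% BLQ excluded)
Population PK parameter estimates (FOCE-I)
OFV 6251.004   AIC 6283.004   n_params 16   n_obs 782
------------------------------------------------------------------------------
Parameter                            Estimate               95% CI   RSE%
CL                                     0.1369                  n/a    n/a L/day
Vc                                      3.035                  n/a    n/a L
Q                                      0.5053                  n/a    n/a L/day
Vp                                       4.43                  n/a    n/a L
...
IIV CL (variance)                     0.06856                  n/a    n/a -  [CV% = 26.6]
Proportional residual (variance)      0.02661                  n/a    n/a -  [CV% = 16.3]
------------------------------------------------------------------------------
Shrinkage eta_cl: 6.3%
Shrinkage eta_vc: 4.5%
```

A 50-subject trial simulated at the published estimates and refit from
randomly perturbed starting values recovers the typical clearance within a
few percent of the generating 0.148 L/day (0.137 here, with the remaining
parameters similarly close); the bracketed CV% values are the derived
coefficient-of-variation transforms of the variance estimates.  With
`compute_covariance=True` (the default) the report also carries 95% CIs
and RSE% from the finite-difference Hessian.

The same pipeline is scriptable from the shell:

```bash
vedopk simulate --seed 1 --out runs/sim
vedopk fit      --data runs/sim/dataset.csv --out runs/fit
vedopk vpc      --data runs/sim/dataset.csv --fit runs/fit --out runs/vpc
vedopk forest   --data runs/sim/dataset.csv --fit runs/fit --out runs/forest
```

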