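# lcsmix

Latent change score mixture modeling of longitudinal symptom panels.

## The problem

Repeated-measurement cohort studies of depressive symptoms — here the
motivating case is a 24-month, nine-wave PHQ-9 panel of 4,361 Norwegian
adults spanning the COVID-19 pandemic — typically report population-level
symptom change, which can mask qualitatively different *trajectories*:
most people stay resilient, some deteriorate mildly, a small group
deteriorates severely, others start high and stay high, and some show an
initial shock followed by fast recovery.  `lcsmix` implements the analytic
pipeline for identifying such trajectory classes and relating them to
baseline risk factors and later clinical outcomes, for biostatisticians
and psychiatric epidemiologists working with wide-format panel data.

## The model

**Latent change score model (LCSM).**  For subject *i* at wave
*t = 1..T*, the true score follows

```
eta_i1            ~  initial level
eta_it  =  eta_i,t-1 + delta_it        (t = 2..T)
y_it    =  eta_it + e_it,   e_it ~ N(0, theta_t)
```

so the latent score vector is a cumulative sum of
(η₁, δ₂, …, δ_T) and nonlinear mean change is captured by the T−1 change
means.  Estimation is full-information maximum likelihood: each subject
contributes the Gaussian log-density of exactly their observed waves, so
partially missing records are retained.  Standard SEM fit indices
(χ² against the saturated model, RMSEA with 90% CI, CFI/TLI, SRMR,
AIC/BIC/aBIC) are computed for the single-class model.

**Mixture extension (LCSMM).**  Discrete latent classes *c = 1..K* carry
all between-person variability: within a class the latent variance is
restricted to zero, so class *c* is a prototypical trajectory
μ_ct = η_c1 + Σ_{s≤t} δ_cs with Gaussian measurement error.  The
observed-data likelihood

```
L = prod_i  sum_c  pi_c  prod_{t observed}  N(y_it; mu_ct, theta_ct)
```

is maximized by multi-start EM (closed-form M-steps, monotone
log-likelihood, replication check across starts).  Class enumeration over
K = 1..Kmax reports information criteria with scree differences, relative
entropy, minimum class size, and log-likelihood replication — it reports,
the analyst decides.

**Bias-adjusted 3-step analyses.**  After fitting the unconditional
mixture, subjects are modally assigned and the assignment error rates
Q[k, s] = P(assigned s | true k) are estimated from the posterior.
Covariate effects on membership (multinomial logit, reference class
configurable) and class-specific probabilities of binary distal outcomes
are then estimated from likelihoods that marginalize over the true class
with the assignment treated as a fallible indicator with known error
rates — avoiding both class redefinition by covariates and the bias of
treating assignments as known.

**Synthetic cohorts.**  The study's raw data are not publicly
depositable, so `lcsmix.simulate` generates cohorts with the published
statistical structure: five trajectory classes (Strong Deterioration
6.77%, Consistently High 8.50%, Mild Deterioration 29.04%,
Shock-to-Resilience 13.17%, Consistent Resilience 42.52%) with tabulated
initial-level and change means, covariate-driven membership whose
log-odds are the published odds ratios (intercepts calibrated so the
marginal proportions match), the observed per-wave retention schedule,
and class-dependent end-of-study outcomes.  See `docs/methods.md` for
every default and its provenance.

## Worked example

```python
from lcsmix.recovery import run_recovery
from lcsmix.report import params_table
from lcsmix.simulate import CLASS_ABBREV

run = run_recovery(seed=1)   # simulate n=4361, fit K=5, align, 3-step
print(params_table(run.fit, CLASS_ABBREV)[
    ["class", "proportion", "eta_t1", "delta_t2", "theta"]
].round(3).to_string(index=False))
print(f"\nrelative entropy: {run.entropy:.3f}")
print(f"3-step OR, living alone -> Strong Deterioration: "
      f"{run.fitted_or('living_alone', 'SD'):.2f}")
```

prints

```
class  proportion  eta_t1  delta_t2  theta
   SD       0.069   5.342    12.815 23.005
   CH       0.068  15.189    -0.700 18.220
   MD       0.296   6.090     2.598 20.027
   SR       0.136  16.786   -12.776 21.720
   CR       0.432   4.674    -1.539 20.111

relative entropy: 0.719
3-step OR, living alone -> Strong Deterioration: 2.88
```

Reading this: the fitted mixing proportions recover the generating class
sizes (e.g. Consistent Resilience 43.2% vs. the generating 42.52%); the
Shock-to-Resilience class's first change mean (−12.78) recovers the
generating initial-shock recovery of −13.50 within sampling error; the
residual variances sit near the generating 4.5² = 20.25; entropy ≈ 0.72
reflects the calibrated class separation; and the error-corrected 3-step
regression returns the living-alone odds ratio near the generating 2.98.

There is also a CLI for shell use:

```sh
lcsmix simulate --seed 1 --out out/sim          # panel.csv + truth.csv
lcsmix fit --data out/sim/panel.csv --classes 5 --out out/fit
lcsmix enumerate --data out/sim/panel.csv --kmax 6 --out out/enum
lcsmix threestep --data out/sim/panel.csv --classes 5 --mode predictors --out out/3step
lcsmix run-all --seed 1 --out out/all           # full pipeline bundle
lcsmix print-config                             # all resolved defaults
```

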