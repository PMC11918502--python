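# Methods

This note documents the models, estimation choices, and simulation design
behind `lcsmix`, including every place where the design was genuinely
open and what the package chose.

## Single-class latent change score model (`lcsmix.lcsm`)

The latent vector x = (η₁, δ₂, …, δ_T) has mean α and covariance Ψ; with
L the lower-triangular matrix of ones, the implied observed moments are
mean = Lα and cov = LΨL′ + Θ, Θ diagonal.  Estimation maximizes the
full-information Gaussian likelihood (subjects grouped by missingness
pattern purely as an optimization; a property test asserts grouping is
semantically neutral).

*Free-parameter set.*  `LcsmSpec` makes every choice explicit: means free
or fixed, var(η₁) and var(δ_t) free/fixed/zero, cov(η₁, δ) and cov(δ, δ)
free or zero, residual variance constant, per-wave, or fixed.  The
default — free means, free latent variances, zero latent covariances,
constant residual variance — is one defensible parameterization, not a
claim to replicate any particular published single-class fit: published
degrees of freedom alone do not pin down the free-parameter set, so the
package exposes the spec rather than guessing.

*Fit indices.*  χ² = 2(LL_sat − LL_model) against a saturated model
estimated by the standard EM algorithm for multivariate-normal missing
data; the independence baseline (free means and variances, zero
covariances) has a closed form on observed cells.  RMSEA uses the n−1
convention; its 90% CI inverts the noncentral χ² CDF by bisection to
1e-8 on the noncentrality.  CFI/TLI are capped at [0, 1]/1.  SRMR is the
root mean square of residual moments standardized by sample SDs, over the
T(T+1)/2 covariance entries plus the T means (mean structure is modeled,
so mean residuals are included).  Residual variances are floored at 1e-4
to prevent degenerate likelihood spikes; estimates at the floor are
flagged as boundary solutions.

## Trajectory mixture (`lcsmix.mixture`)

Within-class latent variance is restricted to zero, so conditional on
class the waves are independent Gaussians around the cumulative class
mean curve and each subject contributes exactly their observed cells
(valid under MAR).  EM with closed-form M-steps:
π_c = mean responsibility; wave means = responsibility-weighted means of
observed scores (η/δ recovered by differencing); θ = responsibility-
weighted residual mean squares under the configured sharing structure.

Choices:

- **Residual-variance sharing** defaults to class-specific,
  time-constant (all estimated parameters class-specific in the source
  model diagram); `shared` and `classwave` structures are available.
  Variance floor 1e-3.
- **Starts**: 50 random starts by default; class mean curves seeded from
  observed (mean-imputed) subject trajectories with k-means++-style
  spread plus small jitter; a short EM pass (tol 1e-6, ≤80 iterations)
  screens all starts and the top 10 are refined to full convergence
  (relative log-likelihood change < 1e-8, ≤1000 iterations).  The best
  log-likelihood must be matched within 1e-3 by a second start, else the
  fit is flagged as non-replicated.
- **Empty classes** (responsibility mass < 1 subject) abort the start,
  which is re-drawn up to 3 times and otherwise flagged — a class is
  never silently dropped.
- The reported log-likelihood is re-evaluated at the returned parameters
  so `loglik == mixture_loglik(params, data)` exactly.
- **Label switching** is resolved by optimal assignment
  (`linear_sum_assignment`) on squared distances between class mean
  curves, applied consistently to parameters and posteriors.
- **Standard errors** come from the numerically inverted observed
  information at the ML solution (multinomial-logit scale for π, log
  scale for θ, delta method back); they do not propagate start-selection
  or calibration uncertainty.
- Relative entropy E = 1 − (−Σᵢ Σ_c p·ln p)/(n ln K) with 0·ln 0 = 0;
  defined for K ≥ 2 only.
- aBIC uses the log((n+2)/24) penalty.

## Class enumeration (`lcsmix.enumeration`)

Fits K = 1..Kmax with the full multi-start protocol and tabulates, per K:
best log-likelihood and its replication flag, AIC/BIC/aBIC with first
differences (scree), relative entropy (K ≥ 2), and the smallest class's
proportion against a 5% screening floor.  A "diminishing returns" elbow —
the smallest K after which every later BIC drop falls below 20%
(configurable) of the largest drop — is highlighted but never applied:
the final choice also rests on substantive interpretability, which a
program cannot automate.  Non-convergent rows are flagged, not dropped.

## Bias-adjusted 3-step analyses (`lcsmix.three_step`)

Step 2 assigns subjects modally (ties broken toward the lower class
index and logged; proportional assignment is provided as an alternative)
and estimates Q[k, s] = Σᵢ p_ik·1[assign_i = s] / Σᵢ p_ik.  Step 3
maximizes likelihoods that treat the assignment as a fallible class
indicator with error rates Q:

- **Covariates**: Σᵢ log Σ_k P(k | zᵢ; γ)·Q[k, aᵢ] over multinomial-logit
  coefficients (analytic gradient; L-BFGS-B to ftol 1e-14).  With Q = I
  this reduces exactly to ordinary multinomial logistic regression
  (tested against an independent implementation to 1e-6).  Predictors
  enter jointly in one model by default; a univariable per-predictor
  mode is provided since either convention is found in applied reports.
  Subjects missing a covariate are dropped listwise with a reported
  count.  Wald SEs from the numerically differentiated observed
  information; |coef| > 10 triggers a separation flag.
- **Distal outcomes**: Σᵢ log Σ_k π_k·Bern(yᵢ; ρ_k)·Q[k, aᵢ] by EM;
  missing outcomes are excluded with a reported count; a constant
  outcome yields degenerate estimates and a flag.  CIs via the observed
  information on the logit scale, delta method back to ρ, clipped to
  [0, 1].

Known limitation: step-3 SEs condition on the step-1 solution and on Q;
first-stage sampling uncertainty is not propagated (the standard
limitation of the approach).

## Synthetic cohort generator (`lcsmix.simulate`)

The generator emulates the data structure the pipeline targets, with
defaults taken from the published estimates of the motivating cohort:

- **Trajectories**: five classes; wave means are cumulative sums of the
  tabulated initial levels and eight change means.  The tabulated
  Strong Deterioration change means sum to +13.14 (endpoint 18.36) while
  the accompanying text reports a cumulative increase of 12.14 (endpoint
  17.36); the generator uses the tabulated values verbatim and does not
  attempt to resolve the discrepancy.
- **Mixing proportions** 0.0677/0.0850/0.2904/0.1317/0.4252 (SD, CH,
  MD, SR, CR).
- **Membership**: multinomial logit on 11 baseline covariates with
  coefficients = ln of the published odds ratios (reference class
  Consistent Resilience); intercepts are calibrated by a fixed-point
  iteration on a 200,000-draw Monte-Carlo covariate sample so the
  marginal class probabilities match the target proportions within
  0.005.  Note that published-OR effects and target marginals can only
  coexist through such calibration.  Marginal 2×2 contingency odds
  ratios in generated cohorts are mildly attenuated relative to the
  conditional coefficients (odds-ratio non-collapsibility when
  marginalizing over the other active covariates, ~9% for living alone);
  the conditional effect is exactly exp(coef) and is what the 3-step
  regression estimates.
- **Covariates** are drawn independently (the joint distribution is not
  published): sex, age bands, education, relationship, ethnic minority,
  and preexisting diagnosis follow the published baseline margins;
  living alone Bernoulli(0.20) and binge drinking Bernoulli(0.05) are
  documented choices; information seeking Binomial(7, 0.40), physical
  activity Binomial(7, 0.45), and financial/occupational worry
  Binomial(6, 0.40) are documented choices spanning their scales.
- **Retention**: wave-wise missing-completely-at-random thinning with
  per-wave probabilities equal to the observed coverage counts
  (4361, 2158, 2239, 1963, 1811, 1405, 1426, 1110, 1269) divided by the
  baseline 4361 — non-monotone, so intermittent return happens, as in
  the source counts.  MCAR matches the reported absence of systematic
  attrition; a score-dependent MAR dropout hook
  (`apply_mar_missingness`, logit shift −slope·(score − mean)) is
  provided for robustness studies.
- **Distal outcomes** depend only on class (the conditional-independence
  assumption implicit in the distal 3-step model).  The published figure
  shows the ordering but not the numbers, so the defaults are documented
  choices preserving SD > MD > CH > {SR, CR}: treatment seeking
  (0.42, 0.20, 0.28, 0.08, 0.06) and end-of-study diagnosis
  (0.48, 0.22, 0.30, 0.09, 0.07).  Outcomes are observed only for
  subjects present at the final wave.
- **Attention checks**: 2.2% mis-response rate, matching the reported
  97.8% pass rate.

### Residual noise and the measurement scale

Residual variances are not published.  The residual SD is a single time-
and class-constant value fixed by a one-time calibration: the value at
which the fitted five-class model's relative entropy on a default-size
cohort is ≈ 0.71, the published class separation.  The committed default
is **4.5 PHQ-9 points** (fitted entropy 0.70–0.73 across cohort seeds).

By default scores stay on the continuous Gaussian scale.  An integer
mode (`integer_scores=True`) rounds and clips to the 0–27 scale as real
PHQ-9 sum scores are recorded; it is not the default because the lowest
class trajectories (means ≈ 3) sit within one residual SD of the scale
floor, and clipping there skews the within-class distributions enough to
bias ML recovery of the generating proportions by up to 0.05–0.10 — an
order of magnitude beyond sampling error — which would defeat the
generator's primary purpose of providing a known truth for validating
the estimation pipeline.  Analyses of real integer-scale panels are
unaffected by this choice; the integer mode exists precisely to study
that misspecification.

### What the generator does not emulate

Within-class latent-trajectory variance (zero by the model's own
restriction), item-level responses and their psychometrics, recruitment
bias, regional stratification and poststratification weighting,
covariate dependence, and any direct covariate effect on trajectories
given class.  Passing recovery tests therefore validates the estimators
under the model's own assumptions; they say nothing about robustness to
violations real cohorts may exhibit (heavy tails, MNAR attrition,
within-class heterogeneity).

### Sampling resolution of recovery checks

At the calibrated separation (entropy ≈ 0.71) and the default retention
(~4 observed waves per subject), the ML sampling SD at n = 4361 is
roughly 1.5 percentage points for the overlapping mid-sized class
proportions (Mild Deterioration / Consistent Resilience boundary) and
roughly 0.6 points for the Shock-to-Resilience first change mean.
Single-cohort recovery checks with tolerances near these magnitudes are
inherently stochastic in the seed; replicate averages are stable.  The
bundled checks verify (and the numbers above derive from) exactly these
experiments via `lcsmix.recovery.run_recovery`.

## Problem sizes used by the test suite

The suite favors one full-size end-to-end run (n = 4361, 50 starts,
shared across tests via a session fixture) plus small, fast unit
cohorts: n = 300–800 with reduced start counts for EM behavior, n = 2000
for LCSM parameter recovery, 10⁵–10⁶ draws for Monte-Carlo oracles of
moments, marginals, and contingency checks.  These sizes are the
package's choices for a suite that a developer can run frequently.

## Degenerate inputs and tie-breaks

Scoring refuses incomplete PHQ-9 item sets rather than imputing.
Posterior ties in modal assignment break toward the lower class index
and are logged.  A zero target proportion fails intercept calibration
loudly.  Classes with zero posterior mass make the classification table
undefined and raise.  Constant distal outcomes return the constant with
a degenerate-CI flag.  Wave-1 retention must be 1 so every subject has
an observed first wave.
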