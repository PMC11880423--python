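# Methods

## The model

Hemoglobin concentration (Hb, g/L) of children aged 6–59 months is modelled
with a Bayesian structured additive *distributional* (location-scale)
regression: both parameters of the response distribution get their own
additive predictor,

```
hb_i ~ N(mu_i, sigma_i^2)
mu_i      = beta_0     + f_age(age_i) + x_i' beta + f_spat(lon_i, lat_i) + ...
log sigma_i = gamma_0  + z_i' gamma + ...
```

The identity link is used for the mean and the log link for the scale, so
any real-valued predictor maps to a valid parameter pair.  Modelling the
scale alongside the mean is what makes *all* severity classes of anemia
estimable from one fit: under the fitted Normal with CDF `F`, the class
probabilities are telescoping differences

```
P(any)      = F(110)            P(mild)   = F(110) − F(100)
P(moderate) = F(100) − F(70)    P(severe) = F(70)
```

using the WHO cutoffs for this age group (left-closed intervals;
110 itself is not anemic).  Classification operates on altitude-adjusted
Hb; the adjustment is the CDC/DHS polynomial
`−0.032·A + 0.022·A²` g/dL with `A` the altitude in thousands of feet,
applied above 1,000 m, and is swappable (or can be disabled) because
survey providers sometimes ship pre-adjusted values.

### Terms and priors

Each term is a (basis, penalty) pair:

| kind              | basis                             | penalty                    |
|-------------------|-----------------------------------|----------------------------|
| linear            | standardized covariate            | none (flat prior)          |
| P-spline          | cubic B-splines, 20 functions     | 2nd-order difference `D'D` |
| spatial tensor    | row-wise Kronecker, 10 per margin | `K_lon ⊗ I + I ⊗ K_lat`    |
| random intercept  | level indicators                  | identity                   |

Knots are equally spaced on the observed covariate range; prediction
outside the range clamps to the boundary (with a logged count) rather
than extrapolating polynomial tails into unsurveyed areas.  Penalized
blocks carry the partially improper Gaussian smoothing prior
`beta ~ N(0, tau² K⁻)` with `tau² ~ InverseGamma(0.001, 0.001)`;
unpenalized coefficients get flat priors.  These are the standard
structured-additive defaults; nothing in the data pipeline depends on
them beyond ordinary sensitivity.

Spatial coordinates enter in degrees (the modelled regions are
continental-scale); distances that matter for analysis — the 20-km buffer
of marginal curves, nearest-pixel admin assignment — use great-circle
(haversine) distance, because degrees are anisotropic.

## Variable selection by noncyclic boosting

Before the Bayesian fit, candidate terms for *both* parameters compete in
one componentwise gradient-boosting loop: each candidate block is fitted
by penalized least squares to the current working gradient
(score/weight, on the predictor scale) of its parameter, and the single
block whose damped update (learning rate 0.1) improves the training
log-likelihood most is updated.  Penalized base learners are weakened to
a common effective-df target (4) so smooth, spatial, and linear terms
compete fairly.  A term's *selection frequency* — the fraction of the
iteration budget it won — is the importance measure; terms at or above a
floor (default 0.05) proceed to MCMC, and intercepts are always kept.

Stopping: the budget is fixed (default 200 iterations), but the loop
halts early once no candidate block carries signal distinguishable from
noise — each block's score statistic `q'(X'X)⁻¹q / w̄` (with `q` the
block's score projection and `w̄` the mean working weight) is
approximately chi-squared with `p` (block size) degrees of freedom under
the null of no remaining effect, and boosting stops when every statistic
is below its 95% quantile.  Without this, a converged fit necessarily
spends its leftover budget on the best-fitting pure-noise block each
iteration, and noise terms accumulate selection frequencies of 0.1–0.2
that no floor can separate from weak true signals.  `stop_rule=None`
restores the pure fixed-budget behaviour.  The budget remains the
frequency denominator either way.

Boosting is selection-only; coefficients are re-estimated from scratch by
MCMC.

## MCMC

Blockwise sampler: each block's coefficients are proposed from the
Gaussian IWLS approximation of their full conditional (precision
`X'WX + K/tau²`, with score and expected-information weight from the
family) and accepted by Metropolis–Hastings with forward and reverse
proposals evaluated at the current and proposed states.  For the Normal
mean the likelihood is exactly quadratic in the predictor, so the IWLS
"proposal" *is* the full conditional and those updates are Gibbs draws
(acceptance 1 by construction); scale blocks are genuine MH updates with
acceptance rates typically 0.9–1.0, logged per block.  Smoothing
variances have conjugate inverse-gamma full conditionals driven by the
penalty quadratic form `beta'K beta` and the penalty rank.  If a proposal
precision is numerically non-positive-definite, a ridge is escalated (and
logged) before giving up.

Defaults: 12,000 iterations, 2,000 burn-in, thinning 10 (1,000 stored
draws).  Each region (mainland sub-Saharan Africa, South Asia,
Madagascar — geographically disconnected) is fitted separately; region is
a top-level label, one model per region.  A Geweke-style split-chain
z-score per block and per-block acceptance rates are reported by
`convergence_diagnostics`.

The posterior predictive is the draw mixture.  PIT values are
`u_i = mean_d F(y_i; mu_di, sigma_di)`; equal-tailed posterior prediction
intervals invert the mixture CDF by vectorized bisection (deterministic,
no resampling noise).

## Mapping and aggregation

Pixel surfaces evaluate the severity probabilities per posterior draw at
every unmasked pixel of a regular grid (20 × 20 km by default) and then
summarize (mean, equal-tailed 95%).  Masked pixels — barren land,
permanent snow/ice, elevation above 3,750 m (mainland SSA, South Asia) or
1,900 m (Madagascar) — emit no estimate.  Age-stratified maps average
prevalence over the integer months of the bin, unweighted (the within-bin
age distribution is not modelled); the nominal upper bin prints as
"(42, 60]" in some displays but observation stops at 59 months, so the
implementation caps at 59.  Non-geo-referenced covariates are fixed at the
training-data global median (numeric) or mode (categorical).  Marginal
curves fix all non-focal covariates at the median/mode of survey records
within a 20-km great-circle buffer of the chosen location.

Admin-level estimates aggregate *per draw*: admin prevalence is the
population-weighted mean of its pixels' prevalences computed draw by
draw, and only then summarized, so credible intervals propagate the joint
posterior.  Affected-children counts multiply each draw by the population
at risk.  Trends between two years classify the percentage-point change
with the symmetric ±2 band (decrease / constant / increase); the printed
country examples are consistent with point differences, which is how the
rule is implemented.

## Validation

The data are split 80/20, by cluster by default so no PSU coordinate
leaks across the partition (record-level splitting is available).  The
held-out partition yields PIT histograms (uniform for a calibrated
predictive; a Kolmogorov–Smirnov distance is reported), the empirical
coverage of the 95% posterior prediction interval (should be ≈ 0.95),
and the Pearson correlation between model-aggregated admin-2 prevalence
and the direct survey proportion per admin-2 unit (design-naive,
cluster-pooled — survey weights are out of scope without real design
variables).

## The synthetic-data generator

Real inputs (restricted child-recode surveys merged with remote-sensing
rasters) are emulated by a generator with full ground truth:

* **Domain**: a 10° × 10° (≈ 1,100 km) country-scale region with 250 PSUs
  of 20 children each by default — about the cluster density of an actual
  DHS country survey (300–600 PSUs per country).
* **Spatial field**: a low-rank Gaussian-kernel basis expansion on a knot
  lattice, normalized pointwise to exact target variance (default
  25 g²/L², range 200 km).  Low-rank, not an exact GP: smoothness is what
  the downstream tensor smooth needs to recover, not covariance
  exactness.
* **Age effect**: a smooth dip reaching its minimum near 14 months
  (−10 g/L) and rising ≈ 0.12 g/L per month thereafter, mirroring the
  qualitative shape seen in this population: anemia risk is highest in
  the second year of life.
* **Covariates**: child-level standardized wealth, cluster-level
  elevation and temperature from deterministic smooth fields (temperature
  follows a lapse rate of −6.5 °C/km), sex, survey year.  Default true
  effects: wealth +3 g/L per SD on the mean; elevation +1.2×10⁻⁴ per m on
  log scale.
* **Cluster dependence**: an optional i.i.d. Normal PSU intercept
  (sd 3 g/L, on by default) emulating multistage-sampling dependence; the
  true within-PSU dependence structure of real surveys is unknown, and
  this stand-in is flagged in the config.
* **Baselines**: mean intercept 108 g/L, scale 12 g/L — producing overall
  any-anemia prevalence near 60%, the right order for high-burden
  regions.

Ground truth: the marginal (population) scale at a pixel includes the PSU
variance, `sqrt(sigma(x)² + sd_cluster²)`, and true prevalence is the
closed-form class probability averaged over integer months (the age
effect enters the Normal CDF nonlinearly, so averaging happens after,
not before).

What the generator does **not** emulate — and hence what passing tests do
not show about real data: DHS sampling weights, stratification and
non-response; measurement error in Hb or in modelled covariate rasters;
non-Normal response shapes; real geography, population rasters, or
admin boundaries (partitions are nested Voronoi cells).

## Problem sizes and numerical choices

The reference validation experiment uses 5,000 children (4,000 train /
1,000 test after the cluster split), 200 boosting iterations, and
12,000 MCMC iterations; replicate experiments (coefficient recovery,
boosting support recovery, PIT sensitivity) use 20–50 replicates at
n = 2,000–4,000 with shorter chains — sizes at which every stochastic
check has comfortable Monte-Carlo margin.  Ties in boosting improvement
break by fixed candidate order (determinism); the smoothing parameter for
base learners is solved by bisection on the effective-df identity;
mixture-CDF inversion brackets at ±10 posterior SD and bisects to 1e-8.
A degenerate (constant) covariate falls back to a unit scale rather than
dividing by zero; clusters unseen at training time predict at zero random
effect.

## Known limitations

* Pointwise credible bands of penalized smooths do not account for
  smoothing bias; across seeds, the true pixel prevalence falls inside
  the 95% band for roughly 85–90% of pixels rather than 95% — a
  well-known property of P-spline intervals, not a bug in the sampler.
* The Normal response family is the default and only shipped family
  besides a fixed-df Student-t used to exercise the interface; skewed or
  kurtotic families would need to be registered by the user.
* Boosting selection frequencies depend on the stopping rule; with the
  pure fixed-budget variant, uninformative terms accumulate nonzero
  frequencies once the fit has converged.
* No spatio-temporal interaction terms: survey year enters additively.
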