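# anemap

Bayesian distributional regression and prevalence mapping for childhood
anemia from geo-referenced hemoglobin surveys.

## The problem

Anemia in children aged 6–59 months is diagnosed from hemoglobin (Hb,
g/L) against WHO cutoffs — any < 110, mild [100, 110), moderate
[70, 100), severe < 70, on altitude-adjusted values.  Estimating *all*
severity classes at high spatial resolution therefore requires the whole
Hb distribution, not just its mean: a location-scale model

```
hb ~ N(mu(x, s), sigma(x)^2)
mu        = beta0 + f(age) + x'beta + f_spat(lon, lat) + ...
log sigma = gamma0 + z'gamma + ...
```

with structured additive predictors (P-spline smooths, a tensor-product
spatial surface, linear effects, random intercepts) for both parameters.
`anemap` implements the full workflow for analysts working with
DHS-style cluster surveys: term selection by noncyclic gradient boosting,
fully Bayesian estimation by MCMC, severity-class probabilities in closed
form from the fitted distribution, pixel-level prevalence maps with
credible intervals, population-weighted aggregation to admin units with
trend and inequality summaries, and predictive validation (PIT
histograms, out-of-sample 95% prediction-interval coverage, admin-2
model-vs-direct correlation).  Because the real microdata are restricted,
the package ships a synthetic-data module that emulates their structure
(cluster sampling, smooth spatial field, strongly non-linear age effect,
covariate effects on mean and scale) with known ground truth, so the
entire pipeline is testable offline.

See `docs/methods.md` for the model, priors, algorithms, and the
generator's scope.

## Worked example

```python
import numpy as np
from anemap import (SimulationConfig, simulate_survey, parse_formula,
                    boost_select, select_terms, split, SplitSpec,
                    sample_posterior, ppi_coverage, severity_probabilities)

# a DHS-like survey: 5,000 children in 250 clusters, known ground truth
survey, truth = simulate_survey(SimulationConfig(seed=1))

# which terms matter, for each distribution parameter?
candidates = (parse_formula("mu ~ s(age_months) + linear(wealth_index) + "
                            "linear(temperature) + linear(elevation) + te(lon,lat)")
              + parse_formula("sigma ~ linear(elevation) + linear(wealth_index)"))
result = boost_select(survey, candidates, n_iter=200, step=0.1)
for (param, term), freq in sorted(result.selection_frequency.items()):
    if freq > 0:
        print(f"{param:6s} {term:22s} {freq:.3f}")

# Bayesian fit of the selected model, validated out of sample
selected = select_terms(result, frequency_floor=0.05)
train, test = split(survey, SplitSpec(unit="cluster", seed=1))
samples = sample_posterior(train, selected["mu"] + selected["sigma"],
                           n_iter=12000, burnin=2000, thin=10, seed=2)
print(f"95% PPI coverage on held-out data: {ppi_coverage(test, samples):.3f}")

# severity probabilities under a fitted (mu, sigma)
p = severity_probabilities(105.0, 13.0)
print(f"any {p.p_any:.3f}  mild {p.p_mild:.3f}  "
      f"moderate {p.p_moderate:.3f}  severe {p.p_severe:.3f}")
```

Output:

```
mu     linear(temperature)    0.275
mu     linear(wealth_index)   0.135
mu     s(age_months)          0.205
mu     te(lon,lat)            0.320
sigma  linear(elevation)      0.065
95% PPI coverage on held-out data: 0.959
any 0.650  mild 0.299  moderate 0.347  severe 0.004
```

The boosting frequencies recover the data-generating terms — the age
spline, wealth and the spatial surface drive mean Hb, elevation the
scale.  (Temperature is also picked up: it is spatially smooth and
correlated with elevation, so it partly proxies the spatial field — the
kind of covariate/space competition real remote-sensing covariates show
too.)  Held-out coverage of the 95% posterior prediction interval sits at
the nominal level, i.e. the fitted distribution is calibrated, and the
severity probabilities telescope (mild + moderate + severe = any).

A command-line interface mirrors the stages:

```
anemap simulate --seed 1 --out-prefix syn
anemap select   syn_survey.csv -f "mu ~ s(age_months) + te(lon,lat)" ...
anemap fit      syn_survey.csv --model-yaml selection_model.yaml
anemap validate syn_test.csv fit
anemap aggregate syn_grid.csv syn_admin.csv fit
```

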