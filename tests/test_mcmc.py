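"""MCMC sampler: conjugate oracles, determinism, prediction, intervals."""

import numpy as np
import pandas as pd
import pytest

from anemap.basis import parse_formula
from anemap.family import StudentTFamily
from anemap.mcmc import (PosteriorSamples, convergence_diagnostics,
                         posterior_prediction_interval, predict_parameters,
                         predictive_cdf, sample_posterior)

from conftest import degenerate_samples


@pytest.fixture(scope="module")
def iid_data():
    rng = np.random.default_rng(42)
    return pd.DataFrame({"hb": rng.normal(110.0, 10.0, 400)})


class TestConjugateOracle:
    def test_intercept_only_fixed_sigma_matches_closed_form(self, iid_data):
        # flat prior, known sigma: posterior is N(ybar, sigma^2 / n) exactly
        sigma = 10.0
        n = len(iid_data)
        samples = sample_posterior(iid_data, [], n_iter=2200, burnin=200,
                                   thin=1, seed=1, fixed_sigma=sigma)
        draws = samples.coefs[("mu", "intercept")][:, 0]
        ybar = iid_data["hb"].mean()
        post_sd = sigma / np.sqrt(n)
        mc_se = post_sd / np.sqrt(len(draws))  # Gibbs draws are independent
        assert abs(draws.mean() - ybar) < 3 * mc_se
        assert 0.9 < draws.var(ddof=1) / post_sd**2 < 1.1

    def test_linear_gaussian_matches_ols_posterior(self, rng):
        # unpenalized linear model, fixed sigma: marginals are the
        # conjugate Bayesian linear-regression posterior
        n, sigma = 500, 8.0
        x = rng.standard_normal(n)
        df = pd.DataFrame({"hb": 100.0 + 4.0 * x + rng.normal(0, sigma, n),
                           "x": x})
        terms = parse_formula("mu ~ linear(x)")
        samples = sample_posterior(df, terms, n_iter=2200, burnin=200, thin=1,
                                   seed=3, fixed_sigma=sigma)
        draws = samples.coefs[("mu", "linear(x)")][:, 0]
        xs = (x - x.mean()) / x.std()  # the design standardizes internally
        X = np.column_stack([np.ones(n), xs])
        coef = np.linalg.solve(X.T @ X, X.T @ df["hb"].to_numpy())
        cov = sigma**2 * np.linalg.inv(X.T @ X)
        mc_se = np.sqrt(cov[1, 1] / len(draws))
        assert abs(draws.mean() - coef[1]) < 3 * mc_se
        assert 0.9 < draws.var(ddof=1) / cov[1, 1] < 1.1


class TestSamplerMechanics:
    def test_same_seed_reproduces_draws(self, iid_data):
        a = sample_posterior(iid_data, [], n_iter=300, burnin=100, thin=2,
                             seed=9)
        b = sample_posterior(iid_data, [], n_iter=300, burnin=100, thin=2,
                             seed=9)
        for k in a.coefs:
            assert np.array_equal(a.coefs[k], b.coefs[k])

    def test_stored_draw_count(self, iid_data):
        s = sample_posterior(iid_data, [], n_iter=500, burnin=100, thin=10,
                             seed=2)
        assert s.n_stored == 40
        assert s.meta["n_stored"] == 40

    def test_acceptance_rates_recorded_and_valid(self, tiny_fit):
        rates = tiny_fit.meta["acceptance_rates"]
        assert set(rates) >= {"mu:intercept", "sigma:intercept"}
        assert all(0 < r <= 1 for r in rates.values())

    def test_row_permutation_leaves_posterior_unchanged(self, iid_data):
        # iid intercept-only model: posterior summaries are exchangeable
        sigma = 10.0
        a = sample_posterior(iid_data, [], n_iter=1200, burnin=200, thin=1,
                             seed=4, fixed_sigma=sigma)
        permuted = iid_data.sample(frac=1.0, random_state=0).reset_index(
            drop=True)
        b = sample_posterior(permuted, [], n_iter=1200, burnin=200, thin=1,
                             seed=5, fixed_sigma=sigma)
        da = a.coefs[("mu", "intercept")][:, 0]
        db = b.coefs[("mu", "intercept")][:, 0]
        mc = sigma / np.sqrt(len(iid_data)) / np.sqrt(len(da))
        assert abs(da.mean() - db.mean()) < 3 * np.sqrt(2) * mc

    def test_invalid_chain_lengths_rejected(self, iid_data):
        with pytest.raises(ValueError):
            sample_posterior(iid_data, [], n_iter=100, burnin=100, seed=0)
        with pytest.raises(ValueError):
            sample_posterior(iid_data, [], n_iter=100, burnin=10, thin=0,
                             seed=0)

    def test_alternative_family_runs_through_sampler(self, rng):
        # the family contract is pluggable: a fixed-shape Student-t fits
        # without any sampler changes
        n = 300
        df = pd.DataFrame({
            "hb": 110 + 8 * rng.standard_t(6, n),
            "x": rng.standard_normal(n),
        })
        samples = sample_posterior(df, parse_formula("mu ~ linear(x)"),
                                   family=StudentTFamily(6.0), n_iter=600,
                                   burnin=100, thin=2, seed=8)
        assert all(np.all(np.isfinite(v)) for v in samples.coefs.values())
        rates = samples.meta["acceptance_rates"]
        assert all(0 < r <= 1 for r in rates.values())
        # mu is not quadratic for Student-t, so MH must sometimes reject
        assert rates["mu:intercept"] < 1.0


class TestPrediction:
    def test_training_records_reproduce_fitted_values(self, tiny_survey,
                                                      tiny_fit):
        survey, _, _ = tiny_survey
        sub = survey.head(20)
        mu_a, sg_a = predict_parameters(tiny_fit, sub)
        mu_b, sg_b = predict_parameters(tiny_fit, survey)
        assert np.allclose(mu_a, mu_b[:, :20])
        assert np.allclose(sg_a, sg_b[:, :20])

    def test_identical_records_identical_predictions(self, tiny_survey,
                                                     tiny_fit):
        survey, _, _ = tiny_survey
        row = survey.head(1)
        double = pd.concat([row, row], ignore_index=True)
        mu, sg = predict_parameters(tiny_fit, double)
        assert np.array_equal(mu[:, 0], mu[:, 1])
        assert np.array_equal(sg[:, 0], sg[:, 1])

    def test_interval_width_shrinks_to_zero_with_level(self, tiny_survey,
                                                       tiny_fit):
        survey, _, _ = tiny_survey
        sub = survey.head(5)
        lo, hi = posterior_prediction_interval(tiny_fit, sub, level=1e-6)
        assert np.all(hi - lo < 0.1)

    def test_intervals_widen_monotonically_with_level(self, tiny_survey,
                                                      tiny_fit):
        survey, _, _ = tiny_survey
        sub = survey.head(5)
        widths = []
        for level in (0.5, 0.8, 0.95):
            lo, hi = posterior_prediction_interval(tiny_fit, sub, level)
            widths.append(hi - lo)
        assert np.all(widths[0] < widths[1])
        assert np.all(widths[1] < widths[2])

    def test_degenerate_posterior_interval_matches_normal_quantiles(
            self, tiny_survey, tiny_fit):
        survey, _, _ = tiny_survey
        sub = survey.head(4)
        deg = degenerate_samples(tiny_fit)
        mu, sg = predict_parameters(deg, sub)
        lo, hi = posterior_prediction_interval(deg, sub, level=0.95)
        assert np.allclose(lo, mu[0] - 1.959963985 * sg[0], atol=1e-5)
        assert np.allclose(hi, mu[0] + 1.959963985 * sg[0], atol=1e-5)

    def test_predictive_cdf_at_predictive_median(self, tiny_survey, tiny_fit):
        survey, _, _ = tiny_survey
        sub = survey.head(4)
        deg = degenerate_samples(tiny_fit)
        mu, _ = predict_parameters(deg, sub)
        u = predictive_cdf(deg, sub, mu[0])
        assert np.allclose(u, 0.5, atol=1e-12)


class TestPersistence:
    def test_save_load_round_trip(self, tiny_survey, tiny_fit, tmp_path):
        survey, _, _ = tiny_survey
        prefix = str(tmp_path / "fit")
        tiny_fit.save(prefix)
        loaded = PosteriorSamples.load(prefix)
        sub = survey.head(10)
        mu_a, sg_a = predict_parameters(tiny_fit, sub)
        mu_b, sg_b = predict_parameters(loaded, sub)
        assert np.allclose(mu_a, mu_b, atol=1e-9)
        assert np.allclose(sg_a, sg_b, atol=1e-9)


class TestDiagnostics:
    def test_geweke_and_acceptance_reported(self, tiny_fit):
        diag = convergence_diagnostics(tiny_fit)
        assert {"parameter", "term", "geweke_z", "acceptance_rate"} <= \
            set(diag.columns)
        assert np.all(np.isfinite(diag["geweke_z"]))
        # a converged chain stays within a loose z band
        assert np.all(np.abs(diag["geweke_z"]) < 5)
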