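"""Shared fixtures: small synthetic surveys and a quick fitted model."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from anemap.basis import parse_formula
from anemap.mcmc import sample_posterior
from anemap.synthdata import SimulationConfig, simulate_survey


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def tiny_survey():
    """Small survey (600 children, 60 PSUs) with the default effects."""
    cfg = SimulationConfig(n_clusters=60, children_per_cluster=10,
                           grid_resolution_km=60.0, seed=5)
    survey, truth = simulate_survey(cfg)
    return survey, truth, cfg


@pytest.fixture(scope="session")
def tiny_fit(tiny_survey):
    """Quick MCMC fit of a mean age-spline + wealth model on tiny_survey."""
    survey, truth, cfg = tiny_survey
    terms = parse_formula("mu ~ s(age_months) + linear(wealth_index)")
    samples = sample_posterior(survey, terms, n_iter=1200, burnin=200,
                               thin=5, seed=7)
    return samples


@pytest.fixture()
def flat_survey():
    """Survey with constant true parameters: Hb ~ N(110, 10) i.i.d."""
    cfg = SimulationConfig(n_clusters=50, children_per_cluster=20,
                           spatial_variance=0.0, cluster_sd=0.0,
                           beta_mu={}, beta_sigma={},
                           age_curve=lambda a: np.zeros_like(
                               np.asarray(a, dtype=float)),
                           mu_intercept=110.0, sigma_baseline=10.0,
                           grid_resolution_km=120.0, seed=21)
    survey, truth = simulate_survey(cfg)
    return survey, truth, cfg


def degenerate_samples(samples, draw_index: int = 0):
    """Collapse a posterior to a single repeated draw (zero-width bands)."""
    from copy import deepcopy

    out = deepcopy(samples)
    out.coefs = {k: np.tile(v[draw_index], (4, 1)) for k, v in out.coefs.items()}
    out.tau2 = {k: np.tile(v[draw_index], 4) for k, v in out.tau2.items()}
    return out
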