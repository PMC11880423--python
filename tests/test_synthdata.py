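"""Synthetic survey generator: determinism, distributions, grids, admins."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from anemap._geo import EARTH_RADIUS_KM
from anemap.anemia import classify_severity
from anemap.synthdata import (SimulationConfig, make_admin_partition,
                              make_pixel_grid, simulate_spatial_field,
                              simulate_survey)


def constant_config(**overrides):
    """Config with constant true parameters Hb ~ N(mu, sigma)."""
    base = dict(n_clusters=50, children_per_cluster=20, spatial_variance=0.0,
                cluster_sd=0.0, beta_mu={}, beta_sigma={},
                age_curve=lambda a: np.zeros_like(np.asarray(a, dtype=float)),
                mu_intercept=110.0, sigma_baseline=10.0,
                grid_resolution_km=120.0, seed=3)
    base.update(overrides)
    return SimulationConfig(**base)


class TestConfigValidation:
    @pytest.mark.parametrize("kwargs", [
        {"n_clusters": 1},
        {"children_per_cluster": 0},
        {"spatial_variance": -1.0},
        {"bbox": (30.0, 30.0, -10.0, 0.0)},
        {"region": "antarctica"},
        {"sigma_baseline": 0.0},
    ])
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SimulationConfig(**kwargs)


@pytest.fixture(scope="module")
def field_grid():
    return make_pixel_grid((30.0, 35.0, -5.0, 0.0), 25.0)


@pytest.fixture(scope="module")
def admin_grid():
    return make_pixel_grid((30.0, 35.0, -5.0, 0.0), 30.0)


class TestSpatialField:
    def test_zero_variance_is_exactly_zero(self, field_grid):
        assert np.all(simulate_spatial_field(field_grid, 0.0, 200.0, 1) == 0.0)

    def test_deterministic_under_seed(self, field_grid):
        a = simulate_spatial_field(field_grid, 25.0, 200.0, 7)
        b = simulate_spatial_field(field_grid, 25.0, 200.0, 7)
        assert np.array_equal(a, b)

    def test_negative_variance_message_names_parameter(self, field_grid):
        with pytest.raises(ValueError, match="variance"):
            simulate_spatial_field(field_grid, -1.0, 200.0, 1)

    def test_replicate_variance_matches_target(self):
        # pointwise variance across replicate fields ~ target variance
        grid = make_pixel_grid((30.0, 40.0, -10.0, 0.0), 22.0)
        target, n_rep = 25.0, 200
        fields = np.stack([simulate_spatial_field(grid, target, 200.0, s)
                           for s in range(n_rep)])
        pixel_var = fields.var(axis=0, ddof=1).mean()
        mc_se = target * np.sqrt(2.0 / (n_rep - 1))
        assert abs(pixel_var - target) < 3 * mc_se
        # mean over pixels, averaged across replicates, is near zero
        assert abs(fields.mean()) < 3 * np.sqrt(target / n_rep)

    def test_smoothness_neighbors_correlated(self, field_grid):
        f = simulate_spatial_field(field_grid, 25.0, 300.0, 5)
        # adjacent 25-km pixels of a 300-km-range field move together
        diffs = np.abs(np.diff(f[:10]))
        assert diffs.max() < np.sqrt(25.0)


class TestSimulateSurvey:
    def test_deterministic_byte_identical(self):
        cfg = constant_config()
        a, _ = simulate_survey(cfg)
        b, _ = simulate_survey(constant_config())
        assert a.to_csv(index=False) == b.to_csv(index=False)

    def test_ages_within_dhs_window(self, tiny_survey):
        survey, _, _ = tiny_survey
        assert survey["age_months"].min() >= 6
        assert survey["age_months"].max() <= 59

    def test_cluster_members_share_location(self, tiny_survey):
        survey, _, _ = tiny_survey
        per_cluster = survey.groupby("cluster_id")[["lon", "lat"]].nunique()
        assert (per_cluster == 1).all().all()

    def test_locations_inside_bbox(self, tiny_survey):
        survey, _, cfg = tiny_survey
        lon_min, lon_max, lat_min, lat_max = cfg.bbox
        assert survey["lon"].between(lon_min, lon_max).all()
        assert survey["lat"].between(lat_min, lat_max).all()

    def test_noise_free_limit_reproduces_mean(self):
        cfg = constant_config(sigma_baseline=1e-6, n_clusters=10,
                              children_per_cluster=5)
        survey, _ = simulate_survey(cfg)
        assert np.allclose(survey["hb"], 110.0, atol=1e-3)

    def test_sample_mean_matches_clt(self):
        # constant mu = 110, sigma = 10, n = 50,000
        cfg = constant_config(n_clusters=2500, children_per_cluster=20,
                              grid_resolution_km=250.0)
        survey, _ = simulate_survey(cfg)
        assert len(survey) == 50_000
        assert abs(survey["hb"].mean() - 110.0) < 3 * 10.0 / np.sqrt(50_000)

    def test_constant_config_hb_is_normal(self):
        cfg = constant_config(n_clusters=500, grid_resolution_km=250.0, seed=9)
        survey, _ = simulate_survey(cfg)  # n = 10,000
        p = stats.kstest(survey["hb"], "norm", args=(110.0, 10.0)).pvalue
        assert p > 0.01

    def test_ground_truth_prevalence_in_unit_interval(self, tiny_survey):
        _, truth, _ = tiny_survey
        prev = truth.true_prevalence
        for c in ("any", "mild", "moderate", "severe"):
            assert prev[c].between(0, 1).all()
        assert np.allclose(prev["mild"] + prev["moderate"] + prev["severe"],
                           prev["any"], atol=1e-12)

    def test_ground_truth_prevalence_matches_monte_carlo(self, rng):
        cfg = constant_config(mu_intercept=105.0, sigma_baseline=14.0)
        _, truth = simulate_survey(cfg)
        pix = 0
        mu = truth.true_mu_surface[pix]
        sigma = truth.true_sigma_surface[pix]
        n = 100_000
        cls = classify_severity(rng.normal(mu, sigma, n))
        p_any = truth.true_prevalence.loc[pix, "any"]
        se = np.sqrt(p_any * (1 - p_any) / n)
        assert abs(np.mean(cls != "none") - p_any) < 3 * se


class TestPixelGrid:
    def test_default_resolution_is_20km(self):
        grid = make_pixel_grid((30.0, 31.0, 0.0, 1.0))
        assert (grid["resolution_km"] == 20.0).all()

    def test_single_pixel_bbox(self):
        # bbox smaller than one pixel collapses to a single cell
        grid = make_pixel_grid((30.0, 30.1, 0.0, 0.1), 20.0)
        assert len(grid) == 1

    def test_100km_square_at_20km_gives_25_pixels(self):
        deg = 100.0 / (np.pi / 180.0 * EARTH_RADIUS_KM)  # 100 km at equator
        grid = make_pixel_grid((0.0, deg, -deg / 2, deg / 2), 20.0)
        assert len(grid) == 25

    def test_degenerate_bbox_rejected(self):
        with pytest.raises(ValueError):
            make_pixel_grid((30.0, 30.0, 0.0, 1.0), 20.0)
        with pytest.raises(ValueError):
            make_pixel_grid((30.0, 31.0, 0.0, 1.0), 0.0)


class TestAdminPartition:
    def test_single_region_contains_everything(self, admin_grid):
        admin = make_admin_partition(admin_grid, 1, 1, seed=0)
        assert admin["admin1"].nunique() == 1
        assert admin["admin2"].nunique() == 1

    def test_partition_exhaustive_and_disjoint(self, admin_grid):
        admin = make_admin_partition(admin_grid, 3, 4, seed=1)
        assert len(admin) == len(admin_grid)
        assert admin["pixel_id"].is_unique
        assert set(admin["pixel_id"]) == set(admin_grid["pixel_id"])

    def test_admin2_nested_in_single_admin1(self, admin_grid):
        admin = make_admin_partition(admin_grid, 3, 4, seed=2)
        parents = admin.groupby("admin2")["admin1"].nunique()
        assert (parents == 1).all()

    def test_more_regions_than_pixels_rejected(self, admin_grid):
        with pytest.raises(ValueError):
            make_admin_partition(admin_grid, len(admin_grid), 2, seed=0)
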