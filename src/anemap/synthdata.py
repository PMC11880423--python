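"""DHS-like synthetic surveys, pixel grids, and admin partitions.

Real inputs for this kind of analysis are restricted-access child-recode
hemoglobin surveys merged with remote-sensing rasters.  This module
generates structurally equivalent data with known ground truth so every
downstream stage (basis construction, boosting selection, MCMC, mapping,
aggregation, calibration) can be exercised and validated end to end:

* cluster (PSU) sampling: all children of a cluster share one geo-coordinate
  and an optional i.i.d. Normal cluster random intercept;
* a smooth mean-zero spatial field (low-rank Gaussian-kernel basis);
* a strongly non-linear age effect on mean Hb with its minimum in the
  12-24 month window, rising thereafter;
* linear covariate effects on the mean and on log scale;
* Normal measurement noise: hb ~ N(mu(x, s), sigma(x)).

The generator never emulates DHS sampling weights, non-response, or real
country geography.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

from ._geo import to_local_km
from .anemia import SEVERITY_CLASSES, SeverityThresholds, severity_probabilities

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "KernelField",
    "default_age_curve",
    "simulate_spatial_field",
    "simulate_survey",
    "make_pixel_grid",
    "make_admin_partition",
    "write_survey_csv",
    "write_grid_csv",
    "write_admin_csv",
]

REGIONS = ("ssa_mainland", "south_asia", "madagascar")

LANDCOVER_CLASSES = ("cropland", "forest", "grassland", "barren", "snow_ice")
_LANDCOVER_PROBS = (0.50, 0.28, 0.17, 0.04, 0.01)


def default_age_curve(age_months):
    """Non-linear age effect on mean Hb (g/L), relative to the intercept.

    Hemoglobin is lowest early in life -- the curve dips to its minimum
    around 14 months -- and rises steadily through the fifth year, so
    anemia prevalence is highest among the youngest children.
    """
    a = np.asarray(age_months, dtype=float)
    out = -10.0 * np.exp(-0.5 * ((a - 15.0) / 10.0) ** 2) + 0.12 * (a - 15.0)
    return out if out.ndim else float(out)


@dataclass
class SimulationConfig:
    """Everything that defines one synthetic survey.

    Coefficients in ``beta_mu`` (g/L per covariate unit) and ``beta_sigma``
    (per covariate unit, on log sigma) are keyed by covariate column name;
    elevation is in meters, temperature in deg C, wealth_index is a
    standardized score.
    """

    n_clusters: int = 250
    children_per_cluster: int = 20
    bbox: tuple[float, float, float, float] = (30.0, 40.0, -10.0, 0.0)
    spatial_variance: float = 25.0          # g/L squared, residual spatial field
    spatial_range_km: float = 200.0
    beta_mu: dict[str, float] = field(default_factory=lambda: {"wealth_index": 3.0})
    beta_sigma: dict[str, float] = field(
        default_factory=lambda: {"elevation": 1.2e-4})
    age_curve: Callable = default_age_curve
    mu_intercept: float = 108.0             # g/L at reference covariates
    sigma_baseline: float = 12.0            # g/L scale at reference covariates
    cluster_sd: float = 3.0                 # g/L; 0 disables the PSU intercept
    region: str = "ssa_mainland"
    survey_years: tuple[int, ...] = (2015,)
    grid_resolution_km: float = 20.0
    seed: int = 0

    def __post_init__(self):
        if self.n_clusters < 2:
            raise ValueError("n_clusters must be >= 2")
        if self.children_per_cluster < 1:
            raise ValueError("children_per_cluster must be >= 1")
        if self.spatial_variance < 0:
            raise ValueError("spatial_variance must be >= 0")
        lon_min, lon_max, lat_min, lat_max = self.bbox
        if not (lon_max > lon_min and lat_max > lat_min):
            raise ValueError("bbox must be non-degenerate (lon_min < lon_max, "
                             "lat_min < lat_max)")
        if self.region not in REGIONS:
            raise ValueError(f"region must be one of {REGIONS}")
        if self.sigma_baseline <= 0:
            raise ValueError("sigma_baseline must be positive")


@dataclass
class GroundTruth:
    """True surfaces and parameters behind one simulated survey.

    Surfaces are evaluated on ``grid`` at the reference covariate profile
    (wealth 0, pixel elevation/temperature, age effect averaged over the
    integer months 6..59, no cluster effect).
    """

    grid: pd.DataFrame
    true_mu_surface: np.ndarray
    true_sigma_surface: np.ndarray
    true_coefficients: dict
    true_prevalence: pd.DataFrame  # columns: any, mild, moderate, severe


class KernelField:
    """Smooth low-rank Gaussian random field, evaluable at any lon/lat.

    The field is a Gaussian-kernel basis expansion over a regular knot
    lattice with i.i.d. standard-Normal coefficients, normalized pointwise
    so every location has mean 0 and variance exactly ``variance``; the
    kernel bandwidth equals ``range_km``, which controls smoothness.  A
    low-rank construction (not an exact GP) -- smoothness, not covariance
    exactness, is what the downstream model needs to recover.
    """

    def __init__(self, bbox, variance: float, range_km: float, rng: np.random.Generator):
        if variance < 0:
            raise ValueError(f"variance must be >= 0, got {variance}")
        if range_km <= 0:
            raise ValueError(f"range_km must be positive, got {range_km}")
        self.variance = float(variance)
        self.range_km = float(range_km)
        lon_min, lon_max, lat_min, lat_max = bbox
        self.lon0 = 0.5 * (lon_min + lon_max)
        self.lat0 = 0.5 * (lat_min + lat_max)
        x_min, y_min = to_local_km(lon_min, lat_min, self.lon0, self.lat0)
        x_max, y_max = to_local_km(lon_max, lat_max, self.lon0, self.lat0)
        pad = 1.5 * range_km
        spacing = range_km / 2.0
        nx = int(np.clip(np.ceil((x_max - x_min + 2 * pad) / spacing) + 1, 4, 35))
        ny = int(np.clip(np.ceil((y_max - y_min + 2 * pad) / spacing) + 1, 4, 35))
        kx = np.linspace(x_min - pad, x_max + pad, nx)
        ky = np.linspace(y_min - pad, y_max + pad, ny)
        gx, gy = np.meshgrid(kx, ky, indexing="ij")
        self.knots = np.column_stack([gx.ravel(), gy.ravel()])
        self.coef = rng.standard_normal(len(self.knots))

    def __call__(self, lon, lat) -> np.ndarray:
        lon = np.atleast_1d(np.asarray(lon, dtype=float))
        lat = np.atleast_1d(np.asarray(lat, dtype=float))
        if self.variance == 0.0:
            return np.zeros(lon.shape)
        x, y = to_local_km(lon, lat, self.lon0, self.lat0)
        pts = np.column_stack([x, y])
        # chunk to bound memory for large grids
        out = np.empty(len(pts))
        h2 = self.range_km**2
        for start in range(0, len(pts), 4096):
            block = pts[start:start + 4096]
            d2 = ((block[:, None, :] - self.knots[None, :, :]) ** 2).sum(axis=2)
            phi = np.exp(-0.5 * d2 / h2)
            norm = np.sqrt((phi * phi).sum(axis=1))
            out[start:start + 4096] = phi @ self.coef / norm
        return np.sqrt(self.variance) * out


def simulate_spatial_field(grid: pd.DataFrame, variance: float, range_km: float,
                           seed: int) -> np.ndarray:
    """One realization of the smooth spatial field on a pixel grid.

    Returns one value per pixel; zero variance yields exactly zeros and the
    field has mean zero (in expectation over realizations) with pointwise
    variance equal to ``variance``.
    """
    if len(grid) == 0:
        raise ValueError("grid must be non-empty")
    if variance < 0:
        raise ValueError(f"variance must be >= 0, got {variance}")
    bbox = (grid["lon"].min(), grid["lon"].max(),
            grid["lat"].min(), grid["lat"].max())
    fld = KernelField(bbox, variance, range_km, np.random.default_rng(seed))
    return fld(grid["lon"].to_numpy(), grid["lat"].to_numpy())


def make_pixel_grid(bbox, resolution_km: float = 20.0) -> pd.DataFrame:
    """Regular pixel grid covering a lon/lat bbox at the given resolution.

    The number of pixels per axis is the bbox extent (in km, measured at
    the bbox center) divided by the resolution, rounded up; centroids are
    evenly spaced.  Default resolution is the 20 x 20 km mapping scale.
    """
    if resolution_km <= 0:
        raise ValueError("resolution_km must be positive")
    lon_min, lon_max, lat_min, lat_max = bbox
    if not (lon_max > lon_min and lat_max > lat_min):
        raise ValueError("bbox must be non-degenerate")
    lon0 = 0.5 * (lon_min + lon_max)
    lat0 = 0.5 * (lat_min + lat_max)
    x_max, _ = to_local_km(lon_max, lat0, lon0, lat0)
    x_min, _ = to_local_km(lon_min, lat0, lon0, lat0)
    _, y_max = to_local_km(lon0, lat_max, lon0, lat0)
    _, y_min = to_local_km(lon0, lat_min, lon0, lat0)
    nx = max(1, int(np.ceil((x_max - x_min) / resolution_km - 1e-9)))
    ny = max(1, int(np.ceil((y_max - y_min) / resolution_km - 1e-9)))
    lon_step = (lon_max - lon_min) / nx
    lat_step = (lat_max - lat_min) / ny
    lons = lon_min + (np.arange(nx) + 0.5) * lon_step
    lats = lat_min + (np.arange(ny) + 0.5) * lat_step
    glon, glat = np.meshgrid(lons, lats, indexing="ij")
    n = nx * ny
    return pd.DataFrame({
        "pixel_id": np.arange(n),
        "lon": glon.ravel(),
        "lat": glat.ravel(),
        "resolution_km": resolution_km,
        "area_km2": resolution_km**2,
        "elevation": np.nan,
        "temperature": np.nan,
        "landcover_class": "",
        "population": np.nan,
        "mask_flag": False,
    })


def make_admin_partition(grid: pd.DataFrame, n_level1: int,
                         n_level2_per_level1: int, seed: int) -> pd.DataFrame:
    """Assign every pixel to a nested country / admin-1 / admin-2 partition.

    Voronoi-style: admin-1 units grow around random seed pixels; admin-2
    units are nested Voronoi cells within each admin-1.  The partition is
    exhaustive and disjoint by construction.
    """
    if n_level1 < 1 or n_level2_per_level1 < 1:
        raise ValueError("region counts must be >= 1")
    n_pix = len(grid)
    if n_level1 * n_level2_per_level1 > n_pix:
        raise ValueError(
            f"requested {n_level1 * n_level2_per_level1} admin-2 regions "
            f"but the grid has only {n_pix} pixels")
    rng = np.random.default_rng(seed)
    xy = grid[["lon", "lat"]].to_numpy()
    seeds1 = xy[rng.choice(n_pix, size=n_level1, replace=False)]
    d1 = ((xy[:, None, :] - seeds1[None, :, :]) ** 2).sum(axis=2)
    admin1 = d1.argmin(axis=1)
    admin2 = np.empty(n_pix, dtype=object)
    for a1 in range(n_level1):
        members = np.flatnonzero(admin1 == a1)
        k = min(n_level2_per_level1, len(members))
        seeds2 = xy[rng.choice(members, size=k, replace=False)]
        d2 = ((xy[members, None, :] - seeds2[None, :, :]) ** 2).sum(axis=2)
        sub = d2.argmin(axis=1)
        for i, pix in enumerate(members):
            admin2[pix] = f"a1_{a1:02d}/a2_{sub[i]:02d}"
    return pd.DataFrame({
        "pixel_id": grid["pixel_id"].to_numpy(),
        "country": "c_00",
        "admin1": [f"a1_{a:02d}" for a in admin1],
        "admin2": admin2.astype(str),
    })


def _covariate_fields(config: SimulationConfig):
    """Deterministic elevation/temperature fields shared by survey and grid."""
    ss = np.random.SeedSequence([config.seed, 101])
    r_elev, r_temp = (np.random.default_rng(s) for s in ss.spawn(2))
    f_elev = KernelField(config.bbox, 1.0, 300.0, r_elev)
    f_temp = KernelField(config.bbox, 1.0, 400.0, r_temp)

    def elevation(lon, lat):
        return np.clip(700.0 + 450.0 * f_elev(lon, lat), 0.0, None)

    def temperature(lon, lat):
        elev_km = elevation(lon, lat) / 1000.0
        return 27.0 - 6.5 * elev_km + 1.2 * f_temp(lon, lat)

    return elevation, temperature


def _linear_predictors(config, df, spatial, elevation_fn=None):
    """True (mu, sigma) for child records in df (without noise)."""
    mu = np.full(len(df), config.mu_intercept, dtype=float)
    mu += np.asarray(config.age_curve(df["age_months"].to_numpy()), dtype=float)
    eta_sigma = np.full(len(df), np.log(config.sigma_baseline))
    for cov, beta in config.beta_mu.items():
        mu += beta * df[cov].to_numpy(dtype=float)
    for cov, beta in config.beta_sigma.items():
        eta_sigma += beta * df[cov].to_numpy(dtype=float)
    mu += spatial
    return mu, np.exp(eta_sigma)


def simulate_survey(config: SimulationConfig) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate one geo-referenced child hemoglobin survey.

    Returns the child-level survey table (one row per child; all children
    of a cluster share lon/lat) and the :class:`GroundTruth` evaluated on
    a pixel grid over the same bbox.
    """
    ss = np.random.SeedSequence([config.seed, 7])
    (r_field, r_cluster, r_child, r_grid) = (
        np.random.default_rng(s) for s in ss.spawn(4))

    lon_min, lon_max, lat_min, lat_max = config.bbox
    spatial_field = KernelField(config.bbox, config.spatial_variance,
                                config.spatial_range_km, r_field)
    elevation_fn, temperature_fn = _covariate_fields(config)

    # clusters (PSUs)
    n_c = config.n_clusters
    c_lon = r_cluster.uniform(lon_min, lon_max, n_c)
    c_lat = r_cluster.uniform(lat_min, lat_max, n_c)
    c_elev = elevation_fn(c_lon, c_lat)
    c_temp = temperature_fn(c_lon, c_lat)
    c_year = r_cluster.choice(np.asarray(config.survey_years), size=n_c)
    c_effect = (r_cluster.normal(0.0, config.cluster_sd, n_c)
                if config.cluster_sd > 0 else np.zeros(n_c))
    c_spatial = spatial_field(c_lon, c_lat)

    # children
    m = config.children_per_cluster
    n = n_c * m
    idx = np.repeat(np.arange(n_c), m)
    df = pd.DataFrame({
        "cluster_id": [f"c{j:04d}" for j in idx],
        "lon": c_lon[idx],
        "lat": c_lat[idx],
        "elevation": c_elev[idx],
        "temperature": c_temp[idx],
        "survey_year": c_year[idx],
        "age_months": r_child.integers(6, 60, n),
        "sex": np.where(r_child.random(n) < 0.5, "female", "male"),
        "wealth_index": r_child.standard_normal(n),
        "region": config.region,
    })
    mu, sigma = _linear_predictors(config, df, c_spatial[idx] + c_effect[idx])
    df.insert(0, "hb", r_child.normal(mu, sigma))

    # ground truth on a pixel grid at the reference covariate profile
    grid = make_pixel_grid(config.bbox, config.grid_resolution_km)
    grid["elevation"] = elevation_fn(grid["lon"].to_numpy(), grid["lat"].to_numpy())
    grid["temperature"] = temperature_fn(grid["lon"].to_numpy(), grid["lat"].to_numpy())
    grid["landcover_class"] = r_grid.choice(LANDCOVER_CLASSES, size=len(grid),
                                            p=_LANDCOVER_PROBS)
    grid["population"] = np.round(r_grid.lognormal(6.5, 1.0, len(grid)))
    months = np.arange(6, 60)
    age_effect = float(np.mean(config.age_curve(months)))
    profile = grid[["lon", "lat", "elevation", "temperature"]].copy()
    profile["wealth_index"] = 0.0
    g_spatial = spatial_field(grid["lon"].to_numpy(), grid["lat"].to_numpy())
    mu_base = np.full(len(grid), config.mu_intercept)
    eta_s = np.full(len(grid), np.log(config.sigma_baseline))
    for cov, beta in config.beta_mu.items():
        mu_base += beta * profile[cov].to_numpy(dtype=float)
    for cov, beta in config.beta_sigma.items():
        eta_s += beta * profile[cov].to_numpy(dtype=float)
    mu_base += g_spatial
    mu_s = mu_base + age_effect
    # marginal (population) scale at a pixel includes the PSU intercept
    # variance: a random child there belongs to a random cluster
    sigma_s = np.sqrt(np.exp(eta_s) ** 2 + config.cluster_sd**2)
    # population prevalence: closed form averaged over the integer months
    # (the age effect enters Phi nonlinearly, so average after, not before)
    acc = {c: np.zeros(len(grid)) for c in SEVERITY_CLASSES[1:]}
    acc["any"] = np.zeros(len(grid))
    for a in months:
        p = severity_probabilities(
            mu_base + float(config.age_curve(a)), sigma_s, SeverityThresholds())
        acc["any"] += p.p_any
        acc["mild"] += p.p_mild
        acc["moderate"] += p.p_moderate
        acc["severe"] += p.p_severe
    prevalence = pd.DataFrame({
        "pixel_id": grid["pixel_id"],
        **{c: acc[c] / len(months) for c in ("any", "mild", "moderate",
                                             "severe")},
    })
    truth = GroundTruth(
        grid=grid,
        true_mu_surface=mu_s,
        true_sigma_surface=sigma_s,
        true_coefficients={
            "mu_intercept": config.mu_intercept,
            "sigma_baseline": config.sigma_baseline,
            **{f"mu:{k}": v for k, v in config.beta_mu.items()},
            **{f"sigma:{k}": v for k, v in config.beta_sigma.items()},
        },
        true_prevalence=prevalence,
    )
    return df, truth


SURVEY_COLUMNS = ["hb", "cluster_id", "lon", "lat", "elevation", "temperature",
                  "survey_year", "age_months", "sex", "wealth_index", "region"]


def write_survey_csv(df: pd.DataFrame, path) -> None:
    """Write a survey table (documented header: hb g/L, age in months,
    wealth_index standardized, elevation m, lon/lat WGS84 degrees)."""
    df.to_csv(path, index=False)


def write_grid_csv(grid: pd.DataFrame, path) -> None:
    """One row per pixel: centroid lon/lat, covariates, population, mask."""
    grid.to_csv(path, index=False)


def write_admin_csv(admin: pd.DataFrame, path) -> None:
    """Pixel -> (country, admin1, admin2) lookup table."""
    admin.to_csv(path, index=False)
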