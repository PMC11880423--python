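"""Pixel-level prevalence surfaces, masks, and marginal-effect curves.

Posterior draws are pushed through the severity-class probabilities at
every pixel of a regular grid (20 x 20 km by default).  Pixels that cannot
meaningfully carry child-population estimates -- barren land, permanent
snow and ice, or extreme elevations (above 3750 m in mainland sub-Saharan
Africa and South Asia, above 1900 m in Madagascar) -- are masked and emit
no estimate.

Age-stratified maps average the prevalence over an integer-month grid
within the age bin (unweighted; the within-bin age distribution of the
population is not modelled).  Non-geo-referenced covariates are fixed at
the training-data global median (numeric) or mode (categorical).

Marginal curves follow the 20-km-buffer convention: at a chosen location,
all covariates other than the focal one are fixed at the median (numeric)
or mode (categorical) of the survey records within a great-circle buffer,
and the focal covariate sweeps an evaluation grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._geo import haversine_km
from .anemia import SeverityThresholds, severity_probabilities
from .mcmc import PosteriorSamples, predict_parameters

__all__ = [
    "MarginalCurveSpec",
    "mask_grid",
    "pixel_prevalence_draws",
    "predict_prevalence_surface",
    "marginal_curve",
    "write_surface_csv",
    "AGE_BINS",
]

# upper bin prints as 60 in some summaries but observation stops at 59 months
AGE_BINS = {"(6,24]": (6, 24), "(24,42]": (24, 42), "(42,59]": (42, 59),
            "all": (5, 59)}

_ELEVATION_CUTOFF_M = {"ssa_mainland": 3750.0, "south_asia": 3750.0,
                       "madagascar": 1900.0}
_MASKED_LANDCOVER = {"barren", "snow_ice", "permanent snow and ice",
                     "permanent_snow_and_ice"}


@dataclass(frozen=True)
class MarginalCurveSpec:
    """Where and along which covariate to evaluate a marginal curve."""

    lon: float
    lat: float
    covariate: str
    grid: np.ndarray = field(default=None)
    buffer_km: float = 20.0

    def __post_init__(self):
        if self.buffer_km <= 0:
            raise ValueError("buffer_km must be positive")


def mask_grid(grid: pd.DataFrame, region: str) -> pd.DataFrame:
    """Set ``mask_flag`` for pixels excluded from map products."""
    if region not in _ELEVATION_CUTOFF_M:
        raise ValueError(f"unknown region label {region!r}; expected one of "
                         f"{sorted(_ELEVATION_CUTOFF_M)}")
    for col in ("elevation", "landcover_class"):
        if col not in grid.columns:
            raise KeyError(f"grid is missing required column {col!r}")
    out = grid.copy()
    lc = out["landcover_class"].astype(str).str.lower().str.strip()
    masked = lc.isin(_MASKED_LANDCOVER) | (out["elevation"]
                                           > _ELEVATION_CUTOFF_M[region])
    out["mask_flag"] = masked.to_numpy()
    return out


def _ages_in_stratum(age_stratum) -> np.ndarray:
    """Integer months covered by a stratum '(lo,hi]' / tuple / 'all'."""
    if isinstance(age_stratum, str):
        if age_stratum not in AGE_BINS:
            raise ValueError(f"unknown age stratum {age_stratum!r}; "
                             f"known: {sorted(AGE_BINS)}")
        lo, hi = AGE_BINS[age_stratum]
    else:
        lo, hi = age_stratum
    lo_m = max(int(np.floor(lo)) + 1, 6)
    hi_m = min(int(np.floor(hi)), 59)
    if hi_m < lo_m:
        raise ValueError(f"empty age stratum ({lo}, {hi}]")
    return np.arange(lo_m, hi_m + 1)


def _pixel_newdata(samples: PosteriorSamples, grid: pd.DataFrame,
                   year: int | None) -> pd.DataFrame:
    """Per-pixel prediction frame: geo covariates from the grid, the rest
    fixed at the training global median/mode."""
    profile = samples.meta.get("train_profile", {})
    needed = set()
    for blist in samples.blocks.values():
        for b in blist:
            needed.update(b.term.covariates)
    nd = pd.DataFrame(index=grid.index)
    for cov in sorted(needed):
        if cov in grid.columns:
            nd[cov] = grid[cov].to_numpy()
        elif cov == "survey_year" and year is not None:
            nd[cov] = year
        elif cov in profile:
            nd[cov] = profile[cov]
        else:
            raise KeyError(f"covariate {cov!r} neither on the grid nor in "
                           "the training profile")
    if year is not None and "survey_year" in nd.columns:
        nd["survey_year"] = year
    return nd


def pixel_prevalence_draws(samples: PosteriorSamples, grid: pd.DataFrame,
                           year: int | None = None, age_stratum="all",
                           thresholds: SeverityThresholds | None = None):
    """Per-draw severity prevalence on the unmasked pixels of a grid.

    Returns ``(pixel_ids, draws)`` where draws maps severity class ->
    array (n_draws, n_unmasked_pixels); within an age stratum the
    prevalence is the unweighted mean over its integer months.
    """
    t = thresholds or SeverityThresholds()
    if "mask_flag" in grid.columns:
        sub = grid.loc[~grid["mask_flag"].astype(bool)].reset_index(drop=True)
    else:
        sub = grid.reset_index(drop=True)
    if len(sub) == 0:
        raise ValueError("no unmasked pixels to predict on")
    months = _ages_in_stratum(age_stratum)
    nd = _pixel_newdata(samples, sub, year)

    age_terms, static_terms = {"mu": [], "sigma": []}, {"mu": [], "sigma": []}
    for param, blist in samples.blocks.items():
        for b in blist:
            (age_terms if "age_months" in b.term.covariates
             else static_terms)[param].append(b)

    def eta_static(param):
        blist = samples.blocks.get(param, [])
        if not blist:
            fixed = samples.meta.get("fixed_sigma")
            return np.full((samples.n_stored, len(sub)), np.log(fixed))
        eta = np.zeros((samples.n_stored, len(sub)))
        for b in static_terms[param]:
            Xn = b.evaluate(nd)
            eta += samples.coefs[(param, b.term.name)] @ Xn.T
        return eta

    base = {p: eta_static(p) for p in ("mu", "sigma")}
    fam = samples.family
    acc = {c: 0.0 for c in ("any", "mild", "moderate", "severe")}
    for month in months:
        nd_m = nd.copy()
        if any(age_terms.values()):
            nd_m["age_months"] = float(month)
        eta = {}
        for param in ("mu", "sigma"):
            e = base[param].copy()
            for b in age_terms[param]:
                Xn = b.evaluate(nd_m)
                e += samples.coefs[(param, b.term.name)] @ Xn.T
            eta[param] = e
        mu = fam.link_inverse(eta["mu"], "mu")
        sigma = fam.link_inverse(eta["sigma"], "sigma")
        probs = severity_probabilities(mu, sigma, t, family=fam)
        acc["any"] += probs.p_any
        acc["mild"] += probs.p_mild
        acc["moderate"] += probs.p_moderate
        acc["severe"] += probs.p_severe
    draws = {c: v / len(months) for c, v in acc.items()}
    return sub["pixel_id"].to_numpy(), draws


def predict_prevalence_surface(samples: PosteriorSamples, grid: pd.DataFrame,
                               year: int | None = None, age_stratum="all",
                               thresholds: SeverityThresholds | None = None
                               ) -> pd.DataFrame:
    """Posterior mean and equal-tailed 95% interval of severity prevalence
    per unmasked pixel.

    Returns a long DataFrame (pixel_id, severity, mean, lower95, upper95)
    with ``year`` and ``age_stratum`` in ``.attrs``.
    """
    pixel_ids, draws = pixel_prevalence_draws(samples, grid, year,
                                              age_stratum, thresholds)
    frames = []
    for severity, arr in draws.items():
        frames.append(pd.DataFrame({
            "pixel_id": pixel_ids,
            "severity": severity,
            "mean": arr.mean(axis=0),
            "lower95": np.quantile(arr, 0.025, axis=0),
            "upper95": np.quantile(arr, 0.975, axis=0),
        }))
    out = pd.concat(frames, ignore_index=True)
    out.attrs["year"] = year
    out.attrs["age_stratum"] = str(age_stratum)
    return out


def buffer_profile(survey: pd.DataFrame, lon: float, lat: float,
                   buffer_km: float = 20.0) -> pd.DataFrame:
    """Median/mode covariate profile of survey records within a
    great-circle buffer around (lon, lat)."""
    d = haversine_km(survey["lon"].to_numpy(), survey["lat"].to_numpy(),
                     lon, lat)
    inside = survey.loc[d <= buffer_km]
    if len(inside) == 0:
        raise ValueError(f"no survey records within {buffer_km} km of "
                         f"({lon}, {lat})")
    profile = {}
    for col in survey.columns:
        s = inside[col]
        if pd.api.types.is_numeric_dtype(s):
            profile[col] = float(s.median())
        else:
            profile[col] = s.mode().iloc[0]
    profile["lon"], profile["lat"] = lon, lat
    return pd.DataFrame([profile])


def marginal_curve(samples: PosteriorSamples, spec: MarginalCurveSpec,
                   survey: pd.DataFrame, severity: str = "any",
                   thresholds: SeverityThresholds | None = None
                   ) -> pd.DataFrame:
    """Marginal severity-prevalence curve along one covariate at a location.

    All other covariates are fixed by the 20-km-buffer median/mode rule;
    the returned frame carries the buffer median of the focal covariate in
    ``.attrs["focal_median"]`` (the dashed reference line of the usual
    display).
    """
    t = thresholds or SeverityThresholds()
    profile = buffer_profile(survey, spec.lon, spec.lat, spec.buffer_km)
    focal = spec.covariate
    if focal not in survey.columns:
        raise KeyError(f"focal covariate {focal!r} not in survey")
    grid_vals = spec.grid
    if grid_vals is None:
        lo, hi = survey[focal].min(), survey[focal].max()
        grid_vals = np.linspace(lo, hi, 50)
    grid_vals = np.asarray(grid_vals, dtype=float)
    nd = pd.concat([profile] * len(grid_vals), ignore_index=True)
    nd[focal] = grid_vals
    mu, sigma = predict_parameters(samples, nd)
    probs = severity_probabilities(mu, sigma, t, family=samples.family)
    arr = getattr(probs, f"p_{severity}")
    out = pd.DataFrame({
        focal: grid_vals,
        "mean": arr.mean(axis=0),
        "lower95": np.quantile(arr, 0.025, axis=0),
        "upper95": np.quantile(arr, 0.975, axis=0),
    })
    out.attrs["focal_median"] = float(profile[focal].iloc[0])
    out.attrs["severity"] = severity
    return out


def write_surface_csv(surface: pd.DataFrame, path) -> None:
    """Write a prevalence surface (pixel_id, severity, mean, lo, hi)."""
    surface.to_csv(path, index=False)
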