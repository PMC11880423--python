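"""Predictive validation: train/test splits, PIT, PPI coverage, admin-2
model-vs-direct correlation.

The model's predictive claims are checked on held-out data: an 80/20
split (by cluster by default, preventing spatial leakage through shared
PSU coordinates), probability-integral-transform histograms (uniform for
a calibrated predictive), the empirical coverage of the equal-tailed 95%
posterior prediction interval (should be about 0.95), and the Pearson
correlation between model-aggregated admin-2 prevalence and the direct
survey proportion per admin-2 unit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial import cKDTree

from ._geo import to_local_km
from .anemia import SeverityThresholds, classify_severity
from .mcmc import PosteriorSamples, posterior_prediction_interval, predictive_cdf

__all__ = [
    "SplitSpec",
    "CalibrationReport",
    "split",
    "pit",
    "ppi_coverage",
    "admin2_validation",
    "assign_admin",
    "direct_admin_estimates",
]


@dataclass(frozen=True)
class SplitSpec:
    """How to partition the survey into training and test data."""

    train_fraction: float = 0.8
    unit: str = "cluster"  # or "record"
    seed: int = 0

    def __post_init__(self):
        if not (0 < self.train_fraction < 1):
            raise ValueError("train_fraction must be in (0, 1)")
        if self.unit not in ("record", "cluster"):
            raise ValueError("unit must be 'record' or 'cluster'")


@dataclass
class CalibrationReport:
    """PIT values/histogram, KS distance to uniform, PPI coverage, and
    (when computed) per-severity admin-2 correlations."""

    pit_values: np.ndarray
    pit_histogram: np.ndarray
    ks_statistic: float
    ks_pvalue: float
    ppi_coverage: float
    ppi_level: float
    admin2_correlation: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "pit_histogram": self.pit_histogram.tolist(),
            "ks_statistic": self.ks_statistic,
            "ks_pvalue": self.ks_pvalue,
            "ppi_coverage": self.ppi_coverage,
            "ppi_level": self.ppi_level,
            "admin2_correlation": self.admin2_correlation,
        }


def split(data: pd.DataFrame, spec: SplitSpec | None = None):
    """Partition the survey into (train, test).

    With ``unit='record'`` exactly round(train_fraction * n) records are
    trained on; with ``unit='cluster'`` whole PSUs are assigned to one
    side so no cluster coordinate leaks across the partition.
    """
    s = spec or SplitSpec()
    rng = np.random.default_rng(s.seed)
    if s.unit == "record":
        n = len(data)
        n_train = int(round(s.train_fraction * n))
        if n_train == 0 or n_train == n:
            raise ValueError("split leaves a partition empty")
        perm = rng.permutation(n)
        train = data.iloc[perm[:n_train]].reset_index(drop=True)
        test = data.iloc[perm[n_train:]].reset_index(drop=True)
        return train, test
    clusters = pd.unique(data["cluster_id"])
    k = len(clusters)
    k_train = int(round(s.train_fraction * k))
    if k_train == 0 or k_train == k:
        raise ValueError("split leaves a partition empty (too few clusters)")
    perm = rng.permutation(k)
    train_ids = set(clusters[perm[:k_train]])
    mask = data["cluster_id"].isin(train_ids).to_numpy()
    return (data.loc[mask].reset_index(drop=True),
            data.loc[~mask].reset_index(drop=True))


def pit(test: pd.DataFrame, samples: PosteriorSamples, bins: int = 10,
        response: str = "hb"):
    """PIT values, histogram and KS distance to Uniform(0, 1).

    ``u_i`` is the posterior-predictive CDF (mixture over draws) at the
    observed response; a calibrated predictive yields uniform u.
    """
    if len(test) == 0:
        raise ValueError("test partition is empty")
    u = predictive_cdf(samples, test, test[response].to_numpy())
    hist, _ = np.histogram(u, bins=bins, range=(0.0, 1.0))
    ks = stats.kstest(u, "uniform")
    return u, hist, float(ks.statistic), float(ks.pvalue)


def ppi_coverage(test: pd.DataFrame, samples: PosteriorSamples,
                 level: float = 0.95, response: str = "hb") -> float:
    """Fraction of held-out responses inside their equal-tailed level-PPI."""
    if len(test) == 0:
        raise ValueError("test partition is empty")
    lower, upper = posterior_prediction_interval(samples, test, level)
    y = test[response].to_numpy(dtype=float)
    return float(np.mean((y >= lower) & (y <= upper)))


def calibration_report(test: pd.DataFrame, samples: PosteriorSamples,
                       level: float = 0.95, bins: int = 10,
                       response: str = "hb") -> CalibrationReport:
    u, hist, ks_stat, ks_p = pit(test, samples, bins, response)
    cov = ppi_coverage(test, samples, level, response)
    return CalibrationReport(pit_values=u, pit_histogram=hist,
                             ks_statistic=ks_stat, ks_pvalue=ks_p,
                             ppi_coverage=cov, ppi_level=level)


def assign_admin(survey: pd.DataFrame, grid: pd.DataFrame) -> pd.DataFrame:
    """Attach admin ids to survey records via the nearest pixel centroid."""
    for c in ("country", "admin1", "admin2"):
        if c not in grid.columns:
            raise KeyError(f"grid is missing admin column {c!r}")
    lon0 = float(grid["lon"].mean())
    lat0 = float(grid["lat"].mean())
    gx, gy = to_local_km(grid["lon"].to_numpy(), grid["lat"].to_numpy(),
                         lon0, lat0)
    sx, sy = to_local_km(survey["lon"].to_numpy(), survey["lat"].to_numpy(),
                         lon0, lat0)
    tree = cKDTree(np.column_stack([gx, gy]))
    _, idx = tree.query(np.column_stack([sx, sy]))
    out = survey.copy()
    for c in ("country", "admin1", "admin2"):
        out[c] = grid[c].to_numpy()[idx]
    return out


def direct_admin_estimates(survey: pd.DataFrame, grid: pd.DataFrame,
                           thresholds: SeverityThresholds | None = None,
                           adjust_altitude: bool = False) -> pd.DataFrame:
    """Design-naive direct survey prevalence per admin-2 unit.

    Records are classified by (optionally altitude-adjusted) Hb and
    cluster-pooled into unweighted proportions per unit and severity.
    """
    from .anemia import adjust_hb_for_altitude

    t = thresholds or SeverityThresholds()
    tagged = assign_admin(survey, grid)
    hb = tagged["hb"].to_numpy(dtype=float)
    if adjust_altitude:
        hb = adjust_hb_for_altitude(hb, tagged["elevation"].to_numpy())
    cls = classify_severity(hb, t)
    tagged = tagged.assign(_class=cls)
    unit = tagged[["country", "admin1", "admin2"]].astype(str).agg("/".join,
                                                                   axis=1)
    tagged = tagged.assign(admin_id=unit)
    rows = []
    for admin_id, g in tagged.groupby("admin_id"):
        n = len(g)
        counts = g["_class"].value_counts()
        p_mild = counts.get("mild", 0) / n
        p_mod = counts.get("moderate", 0) / n
        p_sev = counts.get("severe", 0) / n
        rows.append({"admin_id": admin_id, "n": n,
                     "any": p_mild + p_mod + p_sev, "mild": p_mild,
                     "moderate": p_mod, "severe": p_sev})
    return pd.DataFrame(rows)


def admin2_validation(model_estimates: pd.DataFrame,
                      direct_estimates: pd.DataFrame,
                      severities=("any", "mild", "moderate", "severe")
                      ) -> dict:
    """Pearson correlation between model-aggregated and direct admin-2
    prevalence, per severity class.

    ``model_estimates`` needs columns admin_id + one per severity (posterior
    means); ``direct_estimates`` the same from the survey.  At least three
    common units are required.
    """
    merged = model_estimates.merge(direct_estimates, on="admin_id",
                                   suffixes=("_model", "_direct"))
    if len(merged) < 3:
        raise ValueError(f"need >= 3 admin-2 units with both estimates, "
                         f"got {len(merged)}")
    out = {}
    for sev in severities:
        a = merged[f"{sev}_model"].to_numpy(dtype=float)
        b = merged[f"{sev}_direct"].to_numpy(dtype=float)
        out[sev] = float(stats.pearsonr(a, b).statistic)
    return out
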