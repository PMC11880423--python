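"""WHO anemia severity classification for children aged 6-59 months.

Severity is defined on altitude-adjusted hemoglobin (Hb, g/L):

    any       Hb < 110
    mild      100 <= Hb < 110
    moderate   70 <= Hb < 100
    severe    Hb < 70

All intervals are left-closed, so the four classes (plus "none") partition
the real line.  Under a fitted response distribution with CDF F the class
probabilities are telescoping differences of F at the three thresholds,
which is how prevalence surfaces are computed downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "SeverityThresholds",
    "SeverityProbabilities",
    "adjust_hb_for_altitude",
    "classify_severity",
    "severity_probabilities",
    "SEVERITY_CLASSES",
]

SEVERITY_CLASSES = ("none", "mild", "moderate", "severe")

_FT_PER_M = 3.280839895


@dataclass(frozen=True)
class SeverityThresholds:
    """Hb cutoffs (g/L) for children 6-59 months; WHO defaults."""

    any: float = 110.0
    mild_lower: float = 100.0
    moderate_lower: float = 70.0

    def __post_init__(self):
        if not (0 < self.moderate_lower < self.mild_lower < self.any):
            raise ValueError(
                "thresholds must satisfy 0 < moderate_lower < mild_lower < any, "
                f"got {self.moderate_lower}, {self.mild_lower}, {self.any}"
            )


@dataclass(frozen=True)
class SeverityProbabilities:
    """Class probabilities under a response distribution; p_any telescopes."""

    p_any: np.ndarray
    p_mild: np.ndarray
    p_moderate: np.ndarray
    p_severe: np.ndarray


def adjust_hb_for_altitude(hb, elevation_m):
    """Altitude-adjust measured Hb (g/L) with the CDC/DHS polynomial.

    Red-cell mass rises with altitude, so the same measured Hb reflects a
    lower effective oxygen-carrying capacity at high elevation.  The
    adjustment (in g/dL, converted to g/L here) is

        adj = -0.032 * A + 0.022 * A**2,   A = altitude in thousands of feet,

    subtracted from the measured value for elevations above 1000 m; below
    that it is zero.  The adjustment depends only on elevation (additive in
    Hb) and is monotone in elevation above the activation altitude.

    Parameters
    ----------
    hb : array_like
        Measured hemoglobin, g/L, positive.
    elevation_m : array_like
        Elevation above sea level, meters.

    Returns
    -------
    ndarray or float
        Adjusted hemoglobin, g/L.
    """
    hb = np.asarray(hb, dtype=float)
    elevation_m = np.asarray(elevation_m, dtype=float)
    if not (np.all(np.isfinite(hb)) and np.all(np.isfinite(elevation_m))):
        raise ValueError("hb and elevation must be finite")
    if np.any(hb <= 0):
        raise ValueError("hb must be positive (g/L)")
    adjusted = hb - altitude_adjustment(elevation_m)
    return adjusted if adjusted.ndim else float(adjusted)


def altitude_adjustment(elevation_m):
    """The additive Hb correction (g/L) at a given elevation (m)."""
    elevation_m = np.asarray(elevation_m, dtype=float)
    a_kft = elevation_m * _FT_PER_M / 1000.0
    adj_gdl = -0.032 * a_kft + 0.022 * a_kft**2
    adj = 10.0 * np.where((elevation_m > 1000.0) & (adj_gdl > 0), adj_gdl, 0.0)
    return adj if adj.ndim else float(adj)


def classify_severity(adjusted_hb, thresholds: SeverityThresholds | None = None):
    """Map adjusted Hb (g/L) to one of none/mild/moderate/severe.

    Boundary semantics: each threshold belongs to the class above it
    (110 -> none, 100 -> mild, 70 -> moderate).
    """
    t = thresholds or SeverityThresholds()
    hb = np.asarray(adjusted_hb, dtype=float)
    if not np.all(np.isfinite(hb)):
        raise ValueError("adjusted_hb must be finite")
    out = np.empty(hb.shape, dtype=object)
    out[hb >= t.any] = "none"
    out[(hb >= t.mild_lower) & (hb < t.any)] = "mild"
    out[(hb >= t.moderate_lower) & (hb < t.mild_lower)] = "moderate"
    out[hb < t.moderate_lower] = "severe"
    if out.ndim == 0:
        return str(out[()])
    return out.astype(str)


def severity_probabilities(mu, sigma, thresholds: SeverityThresholds | None = None,
                           family=None) -> SeverityProbabilities:
    """Closed-form severity-class probabilities under the response family.

    With F the CDF of the fitted distribution (Normal by default):
    p_any = F(110), p_mild = F(110) - F(100), p_moderate = F(100) - F(70),
    p_severe = F(70); p_mild + p_moderate + p_severe == p_any by
    construction.

    Parameters
    ----------
    mu, sigma : array_like
        Location (g/L) and scale (g/L, positive) of the Hb distribution.
    thresholds : SeverityThresholds, optional
    family : Family, optional
        Any registered response family; Normal if omitted.
    """
    from .family import NormalFamily

    t = thresholds or SeverityThresholds()
    fam = family or NormalFamily()
    mu = np.asarray(mu, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    if np.any(sigma <= 0):
        raise ValueError("sigma must be positive")
    f_any = fam.cdf(t.any, mu, sigma)
    f_mild = fam.cdf(t.mild_lower, mu, sigma)
    f_mod = fam.cdf(t.moderate_lower, mu, sigma)
    return SeverityProbabilities(
        p_any=f_any,
        p_mild=f_any - f_mild,
        p_moderate=f_mild - f_mod,
        p_severe=f_mod,
    )
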