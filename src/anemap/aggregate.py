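"""Population-weighted aggregation of pixel draws to administrative units.

Aggregation happens on the draw scale -- admin prevalence is computed per
posterior draw as the population-weighted mean of its pixels' prevalences,
and only afterwards summarized -- so credible intervals propagate the full
joint posterior uncertainty.  Affected-children counts multiply each draw
by the population at risk before summarizing.

Trend classification uses the symmetric two-percentage-point band: a
change below -2 points is a decrease, above +2 an increase, anything in
between counts as constant.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "TrendRule",
    "aggregate_admin",
    "affected_children",
    "classify_trend",
    "inequality_summary",
]

_LEVEL_COLS = {"country": ["country"],
               "admin1": ["country", "admin1"],
               "admin2": ["country", "admin1", "admin2"]}


@dataclass(frozen=True)
class TrendRule:
    """Symmetric percentage-point band within which a trend is 'constant'."""

    constant_band: tuple[float, float] = (-2.0, 2.0)

    def __post_init__(self):
        lo, hi = self.constant_band
        if not (lo < 0 < hi) or abs(lo + hi) > 1e-12:
            raise ValueError("constant_band must be symmetric around 0")


def aggregate_admin(prev_draws: np.ndarray, grid: pd.DataFrame,
                    level: str = "admin2"):
    """Population-weighted admin-level prevalence, aggregated per draw.

    Parameters
    ----------
    prev_draws : ndarray (n_draws, n_pixels)
        Per-draw pixel prevalence, aligned with the rows of ``grid``.
    grid : DataFrame
        Must carry ``population`` and the admin id columns for ``level``.
    level : {'country', 'admin1', 'admin2'}

    Returns
    -------
    (summary, draws) : DataFrame with mean / lower95 / upper95 /
        population per unit, and a dict unit-id -> per-draw prevalence.
    """
    if level not in _LEVEL_COLS:
        raise ValueError(f"level must be one of {sorted(_LEVEL_COLS)}")
    cols = _LEVEL_COLS[level]
    for c in cols + ["population"]:
        if c not in grid.columns:
            raise KeyError(f"grid is missing column {c!r}")
    prev_draws = np.asarray(prev_draws, dtype=float)
    if prev_draws.shape[1] != len(grid):
        raise ValueError("prev_draws and grid are misaligned")
    pop = grid["population"].to_numpy(dtype=float)
    if np.any(pop < 0):
        raise ValueError("population must be >= 0")
    unit_ids = grid[cols].astype(str).agg("/".join, axis=1).to_numpy()
    rows, draws_out = [], {}
    for unit in pd.unique(unit_ids):
        sel = unit_ids == unit
        w = pop[sel]
        total = w.sum()
        if total == 0:
            logger.warning("admin unit %s has zero population; skipped", unit)
            continue
        d = prev_draws[:, sel] @ (w / total)
        draws_out[unit] = d
        rows.append({
            "admin_id": unit, "level": level,
            "mean": d.mean(),
            "lower95": np.quantile(d, 0.025),
            "upper95": np.quantile(d, 0.975),
            "population": total,
        })
    if not rows:
        raise ValueError("no admin unit with positive population")
    return pd.DataFrame(rows), draws_out


def affected_children(prev_draws_unit: np.ndarray, population: float) -> dict:
    """Count of affected children: per-draw prevalence x population at risk,
    summarized by mean and equal-tailed 95% interval."""
    if population < 0:
        raise ValueError("population must be >= 0")
    counts = np.asarray(prev_draws_unit, dtype=float) * population
    return {"mean": float(counts.mean()),
            "lower95": float(np.quantile(counts, 0.025)),
            "upper95": float(np.quantile(counts, 0.975))}


def classify_trend(p_start: float, p_end: float,
                   rule: TrendRule | None = None) -> str:
    """Classify a prevalence change (percent scale) as decrease / constant /
    increase using the +-2 percentage-point band."""
    r = rule or TrendRule()
    for p in (p_start, p_end):
        if not (0 <= p <= 100):
            raise ValueError("prevalences must be on the percent scale [0, 100]")
    delta = p_end - p_start
    lo, hi = r.constant_band
    if delta < lo:
        return "decrease"
    if delta > hi:
        return "increase"
    return "constant"


def inequality_summary(admin2_values, country_value: float) -> dict:
    """Within-country inequality: extremes of admin-2 posterior-mean
    prevalence around the country-level estimate."""
    vals = np.asarray(list(admin2_values), dtype=float)
    if vals.size == 0:
        raise ValueError("need at least one admin-2 estimate")
    return {"min": float(vals.min()), "max": float(vals.max()),
            "range": float(vals.max() - vals.min()),
            "country": float(country_value)}
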