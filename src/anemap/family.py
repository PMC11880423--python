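"""Response-distribution families for location-scale distributional regression.

A family bundles everything the boosting and MCMC machinery needs to know
about the response distribution: the log-likelihood, per-observation scores
and expected-information working weights with respect to each *predictor*
(``eta_mu`` on the identity link, ``eta_sigma = log(sigma)`` on the log
link), the CDF/quantile function, and random generation.

Hemoglobin concentrations of young children are modelled as Normal on the
g/L scale; the Normal location-scale family is the default.  Alternative
families can be registered without touching the sampler or booster, which
only speak this interface.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

__all__ = [
    "Family",
    "NormalFamily",
    "StudentTFamily",
    "get_family",
    "register_family",
]

PARAM_NAMES = ("mu", "sigma")


class Family:
    """Abstract two-parameter location-scale family.

    Parameters are linked to unconstrained predictors: ``mu`` via the
    identity link and ``sigma`` via the log link, so any real-valued
    predictor maps to a valid parameter pair.
    """

    name: str = "abstract"
    param_names = PARAM_NAMES

    # -- links ---------------------------------------------------------
    @staticmethod
    def link_inverse(eta: np.ndarray, which: str) -> np.ndarray:
        if which == "mu":
            return eta
        if which == "sigma":
            return np.exp(eta)
        raise ValueError(f"unknown parameter {which!r}")

    @staticmethod
    def link(value: np.ndarray, which: str) -> np.ndarray:
        if which == "mu":
            return np.asarray(value, dtype=float)
        if which == "sigma":
            return np.log(value)
        raise ValueError(f"unknown parameter {which!r}")

    # -- contract ------------------------------------------------------
    def logpdf(self, y, mu, sigma):  # pragma: no cover - abstract
        raise NotImplementedError

    def loglik(self, y, mu, sigma) -> float:
        y = np.asarray(y, dtype=float)
        if not np.all(np.isfinite(y)):
            raise ValueError("response contains non-finite values")
        return float(np.sum(self.logpdf(y, mu, sigma)))

    def score(self, y, mu, sigma, which):  # pragma: no cover - abstract
        raise NotImplementedError

    def weight(self, y, mu, sigma, which):  # pragma: no cover - abstract
        raise NotImplementedError

    def cdf(self, y, mu, sigma):  # pragma: no cover - abstract
        raise NotImplementedError

    def ppf(self, q, mu, sigma):  # pragma: no cover - abstract
        raise NotImplementedError

    def rng(self, mu, sigma, n, seed):  # pragma: no cover - abstract
        raise NotImplementedError

    def quadratic_in_eta(self, which: str) -> bool:
        """True when the log-likelihood is exactly quadratic in the
        predictor of ``which``, so the IWLS proposal is the exact full
        conditional (Gibbs, no Metropolis-Hastings correction needed)."""
        return False


class NormalFamily(Family):
    """Normal (Gaussian) location-scale family, Hb in g/L.

    score/weight conventions (with r = y - mu):
      d l / d eta_mu     = r / sigma^2,        E[-d2 l] = 1 / sigma^2
      d l / d eta_sigma  = r^2 / sigma^2 - 1,  E[-d2 l] = 2
    """

    name = "normal"

    def logpdf(self, y, mu, sigma):
        y = np.asarray(y, dtype=float)
        sigma = np.asarray(sigma, dtype=float)
        if np.any(sigma <= 0):
            raise ValueError("sigma must be positive")
        r = (y - mu) / sigma
        return -0.5 * np.log(2.0 * np.pi) - np.log(sigma) - 0.5 * r * r

    def score(self, y, mu, sigma, which):
        y = np.asarray(y, dtype=float)
        r = y - mu
        if which == "mu":
            return r / sigma**2
        if which == "sigma":
            return r * r / sigma**2 - 1.0
        raise ValueError(f"unknown parameter {which!r}")

    def weight(self, y, mu, sigma, which):
        y = np.asarray(y, dtype=float)
        if which == "mu":
            return np.broadcast_to(1.0 / np.asarray(sigma, float) ** 2, y.shape).copy()
        if which == "sigma":
            return np.full(y.shape, 2.0)
        raise ValueError(f"unknown parameter {which!r}")

    def cdf(self, y, mu, sigma):
        return stats.norm.cdf(y, loc=mu, scale=sigma)

    def ppf(self, q, mu, sigma):
        return stats.norm.ppf(q, loc=mu, scale=sigma)

    def rng(self, mu, sigma, n, seed):
        gen = np.random.default_rng(seed)
        return gen.normal(loc=mu, scale=sigma, size=n)

    def quadratic_in_eta(self, which):
        # Gaussian likelihood is quadratic in mu at fixed sigma.
        return which == "mu"


class StudentTFamily(Family):
    """Student-t location-scale family with fixed degrees of freedom.

    Exists to exercise the family contract (heavier tails than Normal);
    the working weights are the standard expected-information values.
    """

    name = "student_t"

    def __init__(self, df: float = 5.0):
        if df <= 2:
            raise ValueError("df must exceed 2 for a finite variance")
        self.df = float(df)

    def logpdf(self, y, mu, sigma):
        sigma = np.asarray(sigma, dtype=float)
        if np.any(sigma <= 0):
            raise ValueError("sigma must be positive")
        return stats.t.logpdf(np.asarray(y, float), self.df, loc=mu, scale=sigma)

    def score(self, y, mu, sigma, which):
        y = np.asarray(y, dtype=float)
        nu = self.df
        r = (y - mu) / sigma
        u = (nu + 1.0) / (nu + r * r)
        if which == "mu":
            return u * r / sigma
        if which == "sigma":
            return u * r * r - 1.0
        raise ValueError(f"unknown parameter {which!r}")

    def weight(self, y, mu, sigma, which):
        y = np.asarray(y, dtype=float)
        nu = self.df
        if which == "mu":
            w = (nu + 1.0) / ((nu + 3.0) * np.asarray(sigma, float) ** 2)
            return np.broadcast_to(w, y.shape).copy()
        if which == "sigma":
            return np.full(y.shape, 2.0 * nu / (nu + 3.0))
        raise ValueError(f"unknown parameter {which!r}")

    def cdf(self, y, mu, sigma):
        return stats.t.cdf(y, self.df, loc=mu, scale=sigma)

    def ppf(self, q, mu, sigma):
        return stats.t.ppf(q, self.df, loc=mu, scale=sigma)

    def rng(self, mu, sigma, n, seed):
        gen = np.random.default_rng(seed)
        return mu + sigma * gen.standard_t(self.df, size=n)


_REGISTRY: dict[str, type[Family]] = {}


def register_family(cls: type[Family]) -> type[Family]:
    _REGISTRY[cls.name] = cls
    return cls


register_family(NormalFamily)
register_family(StudentTFamily)


def get_family(name: str, **kwargs) -> Family:
    """Instantiate a registered family by name."""
    try:
        cls = _REGISTRY[name]
    except KeyError:
        raise KeyError(
            f"unknown family {name!r}; registered: {sorted(_REGISTRY)}"
        ) from None
    return cls(**kwargs)
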