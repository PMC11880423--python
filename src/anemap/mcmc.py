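"""MCMC for Bayesian structured additive location-scale regression.

The selected model is re-estimated fully Bayesian.  Each design block's
coefficient vector is updated by a Metropolis-Hastings step whose proposal
is the Gaussian IWLS approximation of the full conditional (score and
expected-information weight from the response family); for blocks in which
the log-likelihood is exactly quadratic in the predictor (the Normal mean)
this proposal *is* the full conditional and the update is a Gibbs draw.
Smoothing variances get conjugate inverse-gamma updates from the penalty
quadratic form.

Priors: flat on unpenalized coefficients; partially improper Gaussian
smoothing prior ``beta ~ N(0, tau^2 K^-)`` on each penalized block with
``tau^2 ~ InverseGamma(0.001, 0.001)``.

Posterior predictive machinery (parameter prediction on new data,
equal-tailed posterior prediction intervals, predictive CDF for PIT)
lives here as well, since it is defined entirely by the stored draws and
the design-block metadata.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg

from .basis import DesignBlock, TermSpec, build_design
from .family import Family, NormalFamily, get_family

logger = logging.getLogger(__name__)

__all__ = [
    "PosteriorSamples",
    "sample_posterior",
    "predict_parameters",
    "posterior_prediction_interval",
    "predictive_cdf",
    "convergence_diagnostics",
]

_TAU2_A = 0.001
_TAU2_B = 0.001
_MAX_RIDGE_ESCALATIONS = 8


@dataclass
class PosteriorSamples:
    """Stored MCMC draws plus everything needed to predict on new data."""

    blocks: dict[str, list[DesignBlock]]
    coefs: dict[tuple[str, str], np.ndarray]   # (param, term) -> (n_stored, p)
    tau2: dict[tuple[str, str], np.ndarray]    # penalized blocks only
    family: Family
    meta: dict = field(default_factory=dict)

    @property
    def n_stored(self) -> int:
        return next(iter(self.coefs.values())).shape[0]

    # -- serialization -------------------------------------------------
    def save(self, prefix: str) -> None:
        """Write draws to ``<prefix>_draws.csv`` and metadata (term specs,
        knots, links, seed, acceptance rates) to ``<prefix>_meta.json``."""
        cols, names = [], []
        for key, arr in self.coefs.items():
            for j in range(arr.shape[1]):
                names.append(f"{key[0]}:{key[1]}[{j}]")
                cols.append(arr[:, j])
        for key, arr in self.tau2.items():
            names.append(f"tau2:{key[0]}:{key[1]}")
            cols.append(arr)
        pd.DataFrame(dict(zip(names, cols))).to_csv(f"{prefix}_draws.csv",
                                                    index=False)
        blocks_meta = []
        for param, blist in self.blocks.items():
            for b in blist:
                t = b.term
                blocks_meta.append({
                    "term": {"name": t.name, "kind": t.kind,
                             "covariates": list(t.covariates),
                             "parameter": t.parameter, "n_basis": t.n_basis,
                             "degree": t.degree,
                             "penalty_order": t.penalty_order},
                    "meta": {k: (v.tolist() if isinstance(v, np.ndarray) else v)
                             for k, v in b.meta.items()},
                })
        payload = {"family": self.family.name, "blocks": blocks_meta,
                   "meta": _jsonable(self.meta)}
        with open(f"{prefix}_meta.json", "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def load(cls, prefix: str) -> "PosteriorSamples":
        with open(f"{prefix}_meta.json") as fh:
            payload = json.load(fh)
        draws = pd.read_csv(f"{prefix}_draws.csv")
        blocks: dict[str, list[DesignBlock]] = {"mu": [], "sigma": []}
        coefs, tau2 = {}, {}
        for bm in payload["blocks"]:
            td = bm["term"]
            t = TermSpec(td["name"], td["kind"], tuple(td["covariates"]),
                         td["parameter"], td["n_basis"], td["degree"],
                         td["penalty_order"])
            meta = {k: (np.asarray(v) if isinstance(v, list) else v)
                    for k, v in bm["meta"].items()}
            key = (t.parameter, t.name)
            sel = [c for c in draws.columns
                   if c.startswith(f"{t.parameter}:{t.name}[")]
            sel.sort(key=lambda c: int(c.rsplit("[", 1)[1][:-1]))
            coefs[key] = draws[sel].to_numpy()
            tcol = f"tau2:{t.parameter}:{t.name}"
            if tcol in draws.columns:
                tau2[key] = draws[tcol].to_numpy()
            blocks[t.parameter].append(DesignBlock(t, np.empty((0, len(sel))),
                                                   np.empty((0, 0)), sel, meta))
        fam = get_family(payload["family"])
        return cls(blocks=blocks, coefs=coefs, tau2=tau2, family=fam,
                   meta=payload["meta"])


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def _mvn_precision_logpdf(x, mean, chol_prec):
    """log N(x; mean, P^-1) with P = L L' given lower-triangular L."""
    p = len(x)
    r = x - mean
    v = chol_prec.T @ r
    logdet = 2.0 * np.sum(np.log(np.diag(chol_prec)))
    return 0.5 * logdet - 0.5 * p * np.log(2 * np.pi) - 0.5 * v @ v


def _chol_with_ridge(P):
    ridge = 0.0
    scale = np.trace(P) / P.shape[0]
    for attempt in range(_MAX_RIDGE_ESCALATIONS):
        try:
            return linalg.cholesky(P + ridge * np.eye(P.shape[0]), lower=True)
        except linalg.LinAlgError:
            ridge = scale * 10.0 ** (attempt - 8)
            logger.warning("proposal precision not PD; escalating ridge to %g",
                           ridge)
    raise linalg.LinAlgError("proposal precision remained non-positive-"
                             "definite after ridge escalation")


def sample_posterior(data: pd.DataFrame, terms: list[TermSpec],
                     family: Family | None = None, n_iter: int = 12000,
                     burnin: int = 2000, thin: int = 10, seed: int = 0,
                     response: str = "hb",
                     fixed_sigma: float | None = None) -> PosteriorSamples:
    """Blockwise IWLS-MH / Gibbs sampling of the location-scale model.

    Parameters
    ----------
    data : DataFrame
        Training survey; must contain ``response`` and all covariates.
    terms : list of TermSpec
        Selected terms for both parameters; intercepts are added per
        parameter automatically.
    n_iter, burnin, thin : int
        Chain length; ``(n_iter - burnin) / thin`` draws are stored.
    fixed_sigma : float, optional
        Hold the scale fixed at this value (no sigma blocks) -- used for
        conjugate-oracle checks.
    """
    if not (n_iter > burnin >= 0):
        raise ValueError("need n_iter > burnin >= 0")
    if thin < 1:
        raise ValueError("thin must be >= 1")
    fam = family or NormalFamily()
    rng = np.random.default_rng(seed)
    y = data[response].to_numpy(dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValueError("response contains non-finite values")
    n = len(y)

    design = build_design(data, terms, add_intercepts=True)
    if fixed_sigma is not None:
        if fixed_sigma <= 0:
            raise ValueError("fixed_sigma must be positive")
        design["sigma"] = []

    # state
    beta: dict[tuple[str, str], np.ndarray] = {}
    contrib: dict[tuple[str, str], np.ndarray] = {}
    tau2: dict[tuple[str, str], float] = {}
    for param, blist in design.items():
        for b in blist:
            key = (param, b.term.name)
            beta[key] = np.zeros(b.n_basis)
            contrib[key] = np.zeros(n)
            if b.penalized:
                tau2[key] = 10.0
    # initialize intercepts at the constant MLE
    if ("mu", "intercept") in beta:
        beta[("mu", "intercept")][:] = np.mean(y)
        contrib[("mu", "intercept")][:] = np.mean(y)
    if ("sigma", "intercept") in beta:
        init = np.log(np.std(y) + 1e-12)
        beta[("sigma", "intercept")][:] = init
        contrib[("sigma", "intercept")][:] = init

    def eta_of(param):
        keys = [(param, b.term.name) for b in design[param]]
        if not keys:
            assert param == "sigma"
            return np.full(n, np.log(fixed_sigma))
        return np.sum([contrib[k] for k in keys], axis=0)

    eta = {"mu": eta_of("mu"), "sigma": eta_of("sigma")}

    ranks = {}
    for param, blist in design.items():
        for b in blist:
            if b.penalized:
                ranks[(param, b.term.name)] = np.linalg.matrix_rank(b.K)

    n_stored = (n_iter - burnin + thin - 1) // thin
    store_coef = {k: np.zeros((n_stored, len(v))) for k, v in beta.items()}
    store_tau2 = {k: np.zeros(n_stored) for k in tau2}
    accept = {k: 0 for k in beta}
    proposals = {k: 0 for k in beta}

    def params_of(eta_mu, eta_sigma):
        return fam.link_inverse(eta_mu, "mu"), fam.link_inverse(eta_sigma, "sigma")

    def proposal(block, key, param, eta_param, eta_other_name):
        """IWLS proposal moments for one block at the given state."""
        mu, sigma = (params_of(eta_param, eta["sigma"]) if param == "mu"
                     else params_of(eta["mu"], eta_param))
        s = fam.score(y, mu, sigma, param)
        w = fam.weight(y, mu, sigma, param)
        z_part = contrib[key] + s / w
        X = block.X
        Xw = X * w[:, None]
        P = X.T @ Xw
        if block.penalized:
            P = P + block.K / tau2[key]
        b_vec = Xw.T @ z_part
        L = _chol_with_ridge(P)
        m = linalg.cho_solve((L, True), b_vec)
        return m, L

    stored = 0
    for it in range(n_iter):
        for param in ("mu", "sigma"):
            for block in design[param]:
                key = (param, block.term.name)
                X = block.X
                m, L = proposal(block, key, param, eta[param], None)
                z = rng.standard_normal(len(m))
                beta_prop = m + linalg.solve_triangular(L, z, lower=True,
                                                        trans="T")
                proposals[key] += 1
                if fam.quadratic_in_eta(param):
                    # exact full conditional: Gibbs draw
                    contrib_new = X @ beta_prop
                    eta[param] = eta[param] - contrib[key] + contrib_new
                    contrib[key] = contrib_new
                    beta[key] = beta_prop
                    accept[key] += 1
                    continue
                # Metropolis-Hastings with forward/reverse IWLS proposals
                contrib_prop = X @ beta_prop
                eta_prop = eta[param] - contrib[key] + contrib_prop
                mu_c, sg_c = params_of(eta["mu"], eta["sigma"])
                if param == "mu":
                    mu_p, sg_p = params_of(eta_prop, eta["sigma"])
                else:
                    mu_p, sg_p = params_of(eta["mu"], eta_prop)
                ll_cur = fam.loglik(y, mu_c, sg_c)
                ll_prop = fam.loglik(y, mu_p, sg_p)
                if block.penalized:
                    pen = block.K / tau2[key]
                    lp_cur = -0.5 * beta[key] @ pen @ beta[key]
                    lp_prop = -0.5 * beta_prop @ pen @ beta_prop
                else:
                    lp_cur = lp_prop = 0.0
                lq_fwd = _mvn_precision_logpdf(beta_prop, m, L)
                # reverse proposal built at the proposed state
                contrib_saved = contrib[key]
                contrib[key] = contrib_prop
                m_rev, L_rev = proposal(block, key, param, eta_prop, None)
                contrib[key] = contrib_saved
                lq_rev = _mvn_precision_logpdf(beta[key], m_rev, L_rev)
                log_alpha = (ll_prop + lp_prop + lq_rev) - (ll_cur + lp_cur + lq_fwd)
                if np.log(rng.random()) < log_alpha:
                    beta[key] = beta_prop
                    eta[param] = eta_prop
                    contrib[key] = contrib_prop
                    accept[key] += 1
        # smoothing variances: conjugate inverse gamma
        for key in tau2:
            param, name = key
            block = next(b for b in design[param] if b.term.name == name)
            quad = beta[key] @ block.K @ beta[key]
            shape = _TAU2_A + 0.5 * ranks[key]
            rate = _TAU2_B + 0.5 * quad
            tau2[key] = rate / rng.gamma(shape)
        if it >= burnin and (it - burnin) % thin == 0:
            for k in beta:
                store_coef[k][stored] = beta[k]
            for k in tau2:
                store_tau2[k][stored] = tau2[k]
            stored += 1

    acc_rates = {f"{k[0]}:{k[1]}": accept[k] / max(proposals[k], 1)
                 for k in beta}
    meta = {
        "seed": seed, "n_iter": n_iter, "burnin": burnin, "thin": thin,
        "n_stored": stored, "n_obs": n, "response": response,
        "family": fam.name, "acceptance_rates": acc_rates,
        "fixed_sigma": fixed_sigma,
        "train_profile": _training_profile(data),
    }
    return PosteriorSamples(
        blocks=design,
        coefs={k: v[:stored] for k, v in store_coef.items()},
        tau2={k: v[:stored] for k, v in store_tau2.items()},
        family=fam, meta=meta,
    )


def _training_profile(data: pd.DataFrame) -> dict:
    """Global median (numeric) / mode (categorical) of training covariates,
    used to fix non-geo-referenced covariates for map products."""
    profile = {}
    for col in data.columns:
        s = data[col]
        if pd.api.types.is_numeric_dtype(s):
            profile[col] = float(s.median())
        else:
            profile[col] = s.mode().iloc[0]
    return profile


def predict_parameters(samples: PosteriorSamples, newdata: pd.DataFrame):
    """Per-draw (mu, sigma) for each new record.

    Returns two arrays of shape (n_draws, n_records); covariates outside
    the training range are clamped (logged by the basis module).
    """
    fam = samples.family
    n_new = len(newdata)
    n_draws = samples.n_stored
    out = {}
    for param in ("mu", "sigma"):
        blist = samples.blocks.get(param, [])
        if not blist:
            fixed = samples.meta.get("fixed_sigma")
            eta = np.full((n_draws, n_new), np.log(fixed))
        else:
            eta = np.zeros((n_draws, n_new))
            for b in blist:
                Xn = b.evaluate(newdata)
                eta += samples.coefs[(param, b.term.name)] @ Xn.T
        out[param] = fam.link_inverse(eta, param)
    return out["mu"], out["sigma"]


def predictive_cdf(samples: PosteriorSamples, newdata: pd.DataFrame,
                   y: np.ndarray) -> np.ndarray:
    """Posterior-predictive CDF at observed values (draw mixture).

    ``u_i = mean_d F(y_i; mu_di, sigma_di)`` -- the PIT value of record i.
    """
    mu, sigma = predict_parameters(samples, newdata)
    y = np.asarray(y, dtype=float)
    return samples.family.cdf(y[None, :], mu, sigma).mean(axis=0)


def _mixture_quantile(fam: Family, mu: np.ndarray, sigma: np.ndarray,
                      q: float, tol: float = 1e-8) -> np.ndarray:
    """Equal-tailed quantile of the draw-mixture predictive, by bisection."""
    lo = (mu - 10 * sigma).min(axis=0)
    hi = (mu + 10 * sigma).max(axis=0)
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        F = fam.cdf(mid[None, :], mu, sigma).mean(axis=0)
        above = F >= q
        hi = np.where(above, mid, hi)
        lo = np.where(above, lo, mid)
        if np.max(hi - lo) < tol:
            break
    return 0.5 * (lo + hi)


def posterior_prediction_interval(samples: PosteriorSamples,
                                  newdata: pd.DataFrame,
                                  level: float = 0.95):
    """Equal-tailed posterior prediction interval per new record.

    The predictive mixes parameter draws with response noise; the interval
    is [q_{(1-level)/2}, q_{(1+level)/2}] of that mixture.
    Returns (lower, upper) arrays of length n_records.
    """
    if not (0 < level < 1):
        raise ValueError("level must be in (0, 1)")
    mu, sigma = predict_parameters(samples, newdata)
    alpha = (1.0 - level) / 2.0
    lower = _mixture_quantile(samples.family, mu, sigma, alpha)
    upper = _mixture_quantile(samples.family, mu, sigma, 1.0 - alpha)
    return lower, upper


def convergence_diagnostics(samples: PosteriorSamples) -> pd.DataFrame:
    """Geweke-style split-chain z-scores and acceptance rates per block.

    Compares the mean of the first 10% of stored draws against the last
    50% (averaged over a block's coefficients); |z| above ~3 flags
    non-convergence.
    """
    rows = []
    acc = samples.meta.get("acceptance_rates", {})
    for key, arr in samples.coefs.items():
        m = arr.mean(axis=1)  # average trace over the block's coefficients
        n = len(m)
        a = m[: max(1, n // 10)]
        b = m[n // 2:]
        denom = np.sqrt(a.var(ddof=1) / len(a) + b.var(ddof=1) / len(b)) \
            if len(a) > 1 and len(b) > 1 else np.nan
        z = (a.mean() - b.mean()) / denom if denom and np.isfinite(denom) \
            and denom > 0 else 0.0
        rows.append({"parameter": key[0], "term": key[1], "geweke_z": z,
                     "acceptance_rate": acc.get(f"{key[0]}:{key[1]}", np.nan)})
    return pd.DataFrame(rows)
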