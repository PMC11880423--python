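"""Noncyclic gradient boosting for term selection in location-scale models.

Variable selection stage: before the final Bayesian fit, candidate terms
for *both* distribution parameters compete in a single componentwise
boosting loop.  At every iteration each candidate block is fitted by
penalized least squares to the current working gradient of its parameter's
predictor, and the one block whose (damped) update improves the training
log-likelihood most is updated by ``step`` times its fit.  The fraction of
iterations in which a term wins -- its selection frequency -- is the
variable-importance measure; terms above a frequency floor proceed to the
MCMC stage.

Intercepts are treated as offsets (initialized at the family's constant
MLE) and are always retained.  Penalized base learners are weakened to a
common effective-degrees-of-freedom target so smooth and linear terms
compete on an equal footing, the standard componentwise-boosting device.
Boosting here is selection-only; final inference is by MCMC.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg
from scipy.stats import chi2

from .basis import DesignBlock, TermSpec, _build_block
from .family import Family, NormalFamily

logger = logging.getLogger(__name__)

__all__ = ["BoostResult", "boost_select", "select_terms"]


@dataclass
class BoostResult:
    """Outcome of one boosting run.

    ``selection_frequency`` maps (parameter, term name) to the fraction of
    the iteration budget in which that block was the updated one; the
    frequencies sum to 1 when the full budget was used.
    """

    selection_frequency: dict[tuple[str, str], float]
    update_counts: dict[tuple[str, str], int]
    coefficient_paths: dict[tuple[str, str], np.ndarray]
    loglik_path: np.ndarray
    n_iter: int
    step: float
    terms: dict[tuple[str, str], TermSpec] = field(default_factory=dict)
    offsets: dict[str, float] = field(default_factory=dict)


def _smoothing_parameter(C: np.ndarray, K: np.ndarray, df_target: float) -> float:
    """Solve for lambda with trace[(C + lambda K)^-1 C] = df_target."""
    p = C.shape[0]
    ridge = 1e-8 * np.trace(C) / p
    evals = linalg.eigh(K, C + ridge * np.eye(p), eigvals_only=True)
    evals = np.clip(evals, 0.0, None)
    rank_k = int(np.sum(evals > 1e-10))
    df_min = p - rank_k  # df as lambda -> infinity (penalty null space)
    df_target = float(np.clip(df_target, df_min + 0.1, p))

    def df(lam):
        return float(np.sum(1.0 / (1.0 + lam * evals)))

    lo, hi = 0.0, 1.0
    while df(hi) > df_target and hi < 1e12:
        hi *= 10.0
    for _ in range(100):
        mid = 0.5 * (lo + hi)
        if df(mid) > df_target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


class _BaseLearner:
    """Penalized least-squares fit of one block to a working gradient."""

    def __init__(self, block: DesignBlock, df_target: float):
        self.block = block
        X = block.X
        C = X.T @ X
        p = C.shape[0]
        if block.penalized:
            lam = _smoothing_parameter(C, block.K, df_target)
            A = C + lam * block.K
        else:
            lam = 0.0
            A = C + 1e-10 * np.trace(C) / p * np.eye(p)
        self.lam = lam
        # solver matrix S with coef = S @ u
        self.S = linalg.solve(A, X.T, assume_a="pos")
        self.df = float(np.trace(X @ self.S))
        # unpenalized Gram factor for the score-test stopping rule
        ridge = 1e-9 * max(np.trace(C) / p, 1.0)
        self._chol_C = linalg.cho_factor(C + ridge * np.eye(p))
        self.score_df = p

    def fit(self, u: np.ndarray) -> np.ndarray:
        return self.S @ u

    def score_statistic(self, raw_score: np.ndarray,
                        mean_weight: float) -> float:
        """Blockwise score statistic ~ chi2(p) when the block carries no
        signal beyond the current fit."""
        q = self.block.X.T @ raw_score
        return float(q @ linalg.cho_solve(self._chol_C, q)) / mean_weight


def boost_select(data: pd.DataFrame, candidate_terms: list[TermSpec],
                 family: Family | None = None, n_iter: int = 200,
                 step: float = 0.1, df_base: float = 4.0,
                 response: str = "hb", stop_rule: str | None = "score-test",
                 seed: int | None = None) -> BoostResult:
    """Run noncyclic componentwise boosting over all candidate terms.

    Parameters
    ----------
    data : DataFrame
        Survey table containing ``response`` and all candidate covariates.
    candidate_terms : list of TermSpec
        Candidates for either parameter; intercept specs are ignored
        (intercepts are offsets, always present).
    n_iter : int
        Iteration budget; selection frequencies are counts / n_iter.
    step : float
        Learning rate in (0, 1].
    df_base : float
        Effective-degrees-of-freedom target for penalized base learners.
    stop_rule : {'score-test', None}
        With 'score-test' (default), boosting halts once no candidate
        block carries signal distinguishable from noise: each block's
        score statistic q' (X'X)^-1 q / w-bar (with q the block's score
        projection) is ~ chi2(p) under the null of no remaining effect,
        and the loop stops when every statistic is below its 95% quantile.
        This keeps selection frequencies of uninformative terms near zero
        instead of letting them absorb the leftover budget.  ``None``
        always runs the full budget.  The budget stays the frequency
        denominator either way.
    seed : int, optional
        Unused (the algorithm is deterministic); accepted for interface
        symmetry with the stochastic stages.
    """
    if not candidate_terms or all(t.kind == "intercept" for t in candidate_terms):
        raise ValueError("candidate term set must contain at least one "
                         "non-intercept term")
    if n_iter < 0:
        raise ValueError("n_iter must be >= 0")
    if not (0 < step <= 1):
        raise ValueError("step must be in (0, 1]")
    fam = family or NormalFamily()
    y = data[response].to_numpy(dtype=float)
    n = len(y)

    keys: list[tuple[str, str]] = []
    learners: dict[tuple[str, str], _BaseLearner] = {}
    terms: dict[tuple[str, str], TermSpec] = {}
    for t in candidate_terms:
        if t.kind == "intercept":
            continue
        key = (t.parameter, t.name)
        if key in learners:
            raise ValueError(f"duplicate candidate term {key}")
        block = _build_block(data, t)
        learners[key] = _BaseLearner(block, df_base)
        terms[key] = t
        keys.append(key)

    # offsets: constant MLE of the family
    offsets = {"mu": float(np.mean(y)), "sigma": float(np.log(np.std(y) + 1e-12))}
    eta = {"mu": np.full(n, offsets["mu"]),
           "sigma": np.full(n, offsets["sigma"])}
    coefs = {k: np.zeros(learners[k].block.n_basis) for k in keys}
    paths = {k: np.zeros((n_iter + 1, learners[k].block.n_basis)) for k in keys}
    counts = {k: 0 for k in keys}

    def current_loglik(eta_mu, eta_sigma):
        return fam.loglik(y, fam.link_inverse(eta_mu, "mu"),
                          fam.link_inverse(eta_sigma, "sigma"))

    ll = current_loglik(eta["mu"], eta["sigma"])
    loglik_path = [ll]
    n_done = 0
    if stop_rule not in ("score-test", None):
        raise ValueError(f"unknown stop_rule {stop_rule!r}")
    for it in range(n_iter):
        grads, scores, mean_w = {}, {}, {}
        mu = fam.link_inverse(eta["mu"], "mu")
        sigma = fam.link_inverse(eta["sigma"], "sigma")
        for param in ("mu", "sigma"):
            # working gradient on the predictor scale (score / weight), so
            # blocks of both parameters take comparably sized steps
            raw = fam.score(y, mu, sigma, param)
            w = fam.weight(y, mu, sigma, param)
            grads[param] = raw / w
            scores[param] = raw
            mean_w[param] = float(np.mean(w))
        if stop_rule == "score-test":
            detectable = False
            for key in keys:
                lrn = learners[key]
                t_stat = lrn.score_statistic(scores[key[0]], mean_w[key[0]])
                if t_stat > chi2.ppf(0.95, lrn.score_df):
                    detectable = True
                    break
            if not detectable:
                logger.info("boosting stopped at iteration %d (no block "
                            "with detectable remaining signal)", it)
                break
        best_key, best_ll, best_update = None, -np.inf, None
        for key in keys:
            param = key[0]
            b = learners[key].fit(grads[param])
            delta = step * (learners[key].block.X @ b)
            eta_new = eta[param] + delta
            if param == "mu":
                ll_new = current_loglik(eta_new, eta["sigma"])
            else:
                ll_new = current_loglik(eta["mu"], eta_new)
            if ll_new > best_ll:  # ties broken by fixed candidate order
                best_key, best_ll, best_update = key, ll_new, (b, eta_new)
        if best_ll <= ll + 1e-12:
            logger.info("boosting stopped at iteration %d (no improving "
                        "block)", it)
            break
        b, eta_new = best_update
        eta[best_key[0]] = eta_new
        coefs[best_key] = coefs[best_key] + step * b
        counts[best_key] += 1
        ll = best_ll
        loglik_path.append(ll)
        n_done = it + 1
        for k in keys:
            paths[k][it + 1] = coefs[k]

    denom = max(n_iter, 1)
    freq = {k: counts[k] / denom for k in keys}
    return BoostResult(
        selection_frequency=freq,
        update_counts=counts,
        coefficient_paths={k: paths[k][: n_done + 1] for k in keys},
        loglik_path=np.asarray(loglik_path),
        n_iter=n_iter,
        step=step,
        terms=terms,
        offsets=offsets,
    )


def select_terms(result: BoostResult, frequency_floor: float = 0.05
                 ) -> dict[str, list[TermSpec]]:
    """Threshold selection frequencies into per-parameter term lists.

    Terms whose frequency strictly exceeds zero and is >= the floor are
    kept; intercepts are always retained (they are offsets in boosting and
    unpenalized blocks in the MCMC stage).
    """
    if not (0 <= frequency_floor <= 1):
        raise ValueError("frequency_floor must be in [0, 1]")
    out: dict[str, list[TermSpec]] = {"mu": [], "sigma": []}
    for key, f in result.selection_frequency.items():
        if f > 0 and f >= frequency_floor:
            out[key[0]].append(result.terms[key])
    return out
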