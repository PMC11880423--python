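"""Structured additive design blocks: bases and penalties.

Each term of a structured additive predictor (linear effect, P-spline
smooth, spatial tensor-product smooth, random intercept) is represented by
a :class:`DesignBlock` holding its basis matrix, its symmetric
positive-semidefinite penalty, and enough metadata (knots, centering
constants, factor levels) to evaluate the same basis on new data.

Conventions:

* B-splines use equally spaced knots spanning the observed covariate range,
  with the boundary knot repeated ``degree`` extra times on each side, so
  basis rows are a partition of unity on the whole range.
* Penalties are difference penalties ``K = D' D`` of configurable order.
* Spatial smooths are row-wise Kronecker (tensor) products of two marginal
  B-spline bases with the additive penalty ``K_lon (x) I + I (x) K_lat``.
* Prediction outside the training range clamps the covariate to the
  boundary; the number of clamped values is counted and logged rather than
  silently extrapolating polynomial tails.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import BSpline

logger = logging.getLogger(__name__)

__all__ = [
    "TermSpec",
    "DesignBlock",
    "bspline_basis",
    "difference_penalty",
    "tensor_spatial_basis",
    "build_design",
    "parse_formula",
]

TERM_KINDS = ("intercept", "linear", "pspline", "spatial_tensor", "random_intercept")


@dataclass(frozen=True)
class TermSpec:
    """One structured additive term of a distribution parameter's predictor."""

    name: str
    kind: str
    covariates: tuple[str, ...]
    parameter: str = "mu"
    n_basis: int = 20
    degree: int = 3
    penalty_order: int = 2

    def __post_init__(self):
        if self.kind not in TERM_KINDS:
            raise ValueError(f"unknown term kind {self.kind!r}")
        if self.kind in ("pspline", "spatial_tensor"):
            if self.n_basis <= self.degree:
                raise ValueError(
                    f"term {self.name!r}: n_basis ({self.n_basis}) must exceed "
                    f"degree ({self.degree})"
                )
            if self.penalty_order < 1:
                raise ValueError("penalty_order must be >= 1 for penalized terms")
        if self.parameter not in ("mu", "sigma"):
            raise ValueError(f"parameter must be 'mu' or 'sigma', got {self.parameter!r}")

    def to_string(self) -> str:
        """Formula-style representation (inverse of :func:`parse_formula`)."""
        if self.kind == "intercept":
            return "1"
        if self.kind == "linear":
            return f"linear({self.covariates[0]})"
        if self.kind == "pspline":
            return f"s({self.covariates[0]})"
        if self.kind == "spatial_tensor":
            return f"te({self.covariates[0]},{self.covariates[1]})"
        return f"re({self.covariates[0]})"


@dataclass
class DesignBlock:
    """Basis matrix + penalty + evaluation metadata for one term."""

    term: TermSpec
    X: np.ndarray
    K: np.ndarray
    column_names: list[str]
    meta: dict = field(default_factory=dict)

    @property
    def n_basis(self) -> int:
        return self.X.shape[1]

    @property
    def penalized(self) -> bool:
        return bool(np.any(self.K))

    def evaluate(self, data: pd.DataFrame) -> np.ndarray:
        """Rebuild the basis on new data using the stored training metadata."""
        t = self.term
        if t.kind == "intercept":
            return np.ones((len(data), 1))
        if t.kind == "linear":
            x = _get_column(data, t.covariates[0])
            return ((x - self.meta["center"]) / self.meta["scale"])[:, None]
        if t.kind == "pspline":
            x = _get_column(data, t.covariates[0])
            x = _clamp(x, self.meta["lo"], self.meta["hi"], t.covariates[0])
            return _bspline_design(x, self.meta["knots"], t.degree)
        if t.kind == "spatial_tensor":
            lon = _get_column(data, t.covariates[0])
            lat = _get_column(data, t.covariates[1])
            lon = _clamp(lon, self.meta["lo_lon"], self.meta["hi_lon"], t.covariates[0])
            lat = _clamp(lat, self.meta["lo_lat"], self.meta["hi_lat"], t.covariates[1])
            b1 = _bspline_design(lon, self.meta["knots_lon"], t.degree)
            b2 = _bspline_design(lat, self.meta["knots_lat"], t.degree)
            return _row_kron(b1, b2)
        if t.kind == "random_intercept":
            x = data[t.covariates[0]].to_numpy()
            levels = self.meta["levels"]
            index = {lv: i for i, lv in enumerate(levels)}
            Z = np.zeros((len(x), len(levels)))
            for row, value in enumerate(x):
                j = index.get(value)
                if j is not None:  # unseen levels predict at zero effect
                    Z[row, j] = 1.0
            return Z
        raise AssertionError(t.kind)


def _get_column(data: pd.DataFrame, name: str) -> np.ndarray:
    if name not in data.columns:
        raise KeyError(f"covariate {name!r} not found in data")
    x = data[name].to_numpy(dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError(f"covariate {name!r} contains non-finite values")
    return x


def _clamp(x: np.ndarray, lo: float, hi: float, name: str) -> np.ndarray:
    n_out = int(np.sum((x < lo) | (x > hi)))
    if n_out:
        logger.warning(
            "%d value(s) of %s outside training range [%g, %g]; clamped",
            n_out, name, lo, hi,
        )
    return np.clip(x, lo, hi)


def _knot_sequence(lo: float, hi: float, n_basis: int, degree: int) -> np.ndarray:
    """Equally spaced knots on [lo, hi] with degree-fold boundary extension."""
    n_interior_intervals = n_basis - degree
    if hi <= lo:
        hi = lo + 1.0  # degenerate constant covariate
    inner = np.linspace(lo, hi, n_interior_intervals + 1)
    step = inner[1] - inner[0]
    left = lo - step * np.arange(degree, 0, -1)
    right = hi + step * np.arange(1, degree + 1)
    return np.concatenate([left, inner, right])


def _bspline_design(x: np.ndarray, knots: np.ndarray, degree: int) -> np.ndarray:
    return BSpline.design_matrix(x, knots, degree, extrapolate=False).toarray()


def bspline_basis(x, n_basis: int, degree: int = 3, knots: np.ndarray | None = None):
    """B-spline basis matrix on equally spaced knots.

    Rows are a partition of unity for ``x`` inside the knot range.

    Returns
    -------
    (B, knots) : design matrix of shape (len(x), n_basis) and the full knot
        sequence (for re-evaluation on new data).
    """
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("x must be finite")
    if n_basis <= degree:
        raise ValueError(f"n_basis ({n_basis}) must exceed degree ({degree})")
    if knots is None:
        knots = _knot_sequence(float(x.min()), float(x.max()), n_basis, degree)
    return _bspline_design(x, knots, degree), knots


def difference_penalty(n_basis: int, order: int = 2) -> np.ndarray:
    """P-spline difference penalty ``K = D' D`` of the given order.

    ``K`` is symmetric PSD with rank ``n_basis - order``; its null space
    contains polynomials in the coefficient index up to degree
    ``order - 1`` (so constants are never penalized for order >= 1).
    """
    if order < 1:
        raise ValueError("order must be >= 1")
    if order >= n_basis:
        raise ValueError(f"order ({order}) must be < n_basis ({n_basis})")
    D = np.diff(np.eye(n_basis), n=order, axis=0)
    return D.T @ D


def _row_kron(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Row-wise Kronecker (face-splitting) product."""
    return (a[:, :, None] * b[:, None, :]).reshape(a.shape[0], -1)


def tensor_spatial_basis(lon, lat, n_basis_per_margin: int = 10, degree: int = 3,
                         penalty_order: int = 2):
    """Tensor-product spatial basis with an additive difference penalty.

    Returns
    -------
    (B, K, meta) : basis of shape (n, m*m), penalty ``K_lon (x) I + I (x)
        K_lat`` of shape (m*m, m*m), and knot metadata.
    """
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    if lon.shape != lat.shape:
        raise ValueError("lon and lat must have the same length")
    b_lon, knots_lon = bspline_basis(lon, n_basis_per_margin, degree)
    b_lat, knots_lat = bspline_basis(lat, n_basis_per_margin, degree)
    B = _row_kron(b_lon, b_lat)
    k1 = difference_penalty(n_basis_per_margin, penalty_order)
    eye = np.eye(n_basis_per_margin)
    K = np.kron(k1, eye) + np.kron(eye, k1)
    meta = {"knots_lon": knots_lon, "knots_lat": knots_lat}
    return B, K, meta


def _build_block(data: pd.DataFrame, t: TermSpec) -> DesignBlock:
    n = len(data)
    if t.kind == "intercept":
        return DesignBlock(t, np.ones((n, 1)), np.zeros((1, 1)),
                           [f"{t.parameter}:{t.name}"])
    if t.kind == "linear":
        x = _get_column(data, t.covariates[0])
        center = float(x.mean())
        scale = float(x.std())
        if scale == 0.0:
            scale = 1.0
        X = ((x - center) / scale)[:, None]
        return DesignBlock(t, X, np.zeros((1, 1)), [f"{t.parameter}:{t.name}"],
                           {"center": center, "scale": scale})
    if t.kind == "pspline":
        x = _get_column(data, t.covariates[0])
        lo, hi = float(x.min()), float(x.max())
        B, knots = bspline_basis(x, t.n_basis, t.degree)
        K = difference_penalty(t.n_basis, t.penalty_order)
        names = [f"{t.parameter}:{t.name}[{j}]" for j in range(t.n_basis)]
        return DesignBlock(t, B, K, names, {"knots": knots, "lo": lo, "hi": hi})
    if t.kind == "spatial_tensor":
        lon = _get_column(data, t.covariates[0])
        lat = _get_column(data, t.covariates[1])
        B, K, meta = tensor_spatial_basis(lon, lat, t.n_basis, t.degree,
                                          t.penalty_order)
        meta.update(lo_lon=float(lon.min()), hi_lon=float(lon.max()),
                    lo_lat=float(lat.min()), hi_lat=float(lat.max()))
        names = [f"{t.parameter}:{t.name}[{j}]" for j in range(B.shape[1])]
        return DesignBlock(t, B, K, names, meta)
    if t.kind == "random_intercept":
        col = t.covariates[0]
        if col not in data.columns:
            raise KeyError(f"covariate {col!r} not found in data")
        levels = sorted(pd.unique(data[col]))
        index = {lv: i for i, lv in enumerate(levels)}
        Z = np.zeros((n, len(levels)))
        Z[np.arange(n), [index[v] for v in data[col]]] = 1.0
        names = [f"{t.parameter}:{t.name}[{lv}]" for lv in levels]
        return DesignBlock(t, Z, np.eye(len(levels)), names, {"levels": levels})
    raise AssertionError(t.kind)


def build_design(data: pd.DataFrame, term_specs: list[TermSpec],
                 add_intercepts: bool = True) -> dict[str, list[DesignBlock]]:
    """Build per-parameter lists of design blocks, deterministically ordered.

    An intercept block is prepended for every distribution parameter unless
    already present (or disabled).  Blocks keep their spec order otherwise.
    """
    design: dict[str, list[DesignBlock]] = {"mu": [], "sigma": []}
    for param in design:
        specs = [t for t in term_specs if t.parameter == param]
        if add_intercepts and not any(t.kind == "intercept" for t in specs):
            specs.insert(0, TermSpec("intercept", "intercept", (), parameter=param))
        for t in specs:
            design[param].append(_build_block(data, t))
    return design


_TERM_RE = re.compile(r"^(1|linear|s|te|re)\s*(?:\(\s*([^)]*?)\s*\))?$")
_KINDS = {"linear": "linear", "s": "pspline", "te": "spatial_tensor",
          "re": "random_intercept"}


def parse_formula(formula: str, n_basis: int = 20, degree: int = 3,
                  penalty_order: int = 2,
                  n_basis_spatial: int = 10) -> list[TermSpec]:
    """Parse ``"mu ~ 1 + linear(wealth) + s(age) + te(lon,lat)"`` into specs.

    ``s()`` builds a P-spline with `n_basis` functions, ``te()`` a spatial
    tensor with `n_basis_spatial` per margin, ``re()`` a random intercept.
    The bare ``1`` intercept may be omitted; it is added at design time.
    """
    if "~" not in formula:
        raise ValueError(f"formula must contain '~': {formula!r}")
    lhs, rhs = (part.strip() for part in formula.split("~", 1))
    if lhs not in ("mu", "sigma"):
        raise ValueError(f"left-hand side must be 'mu' or 'sigma', got {lhs!r}")
    specs: list[TermSpec] = []
    for raw in rhs.split("+"):
        token = raw.strip()
        if not token:
            continue
        m = _TERM_RE.match(token)
        if m is None:
            raise ValueError(f"cannot parse term {token!r}")
        head, args = m.group(1), m.group(2)
        if head == "1":
            specs.append(TermSpec("intercept", "intercept", (), parameter=lhs))
            continue
        covs = tuple(a.strip() for a in (args or "").split(",") if a.strip())
        kind = _KINDS[head]
        if kind == "spatial_tensor":
            if len(covs) != 2:
                raise ValueError(f"te() needs two covariates, got {token!r}")
            nb = n_basis_spatial
        else:
            if len(covs) != 1:
                raise ValueError(f"{head}() needs one covariate, got {token!r}")
            nb = n_basis
        name = f"{head}({','.join(covs)})"
        specs.append(TermSpec(name, kind, covs, parameter=lhs, n_basis=nb,
                              degree=degree, penalty_order=penalty_order))
    return specs
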