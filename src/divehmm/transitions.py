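"""Covariate-driven transition probabilities.

Off-diagonal predictors eta_ij(t) are linear in an intercept plus spline
terms of the three covariate processes:

* ``T`` — natural cubic spline (df 3 by default) in tau_t, the hours since
  the last deep dive;
* ``D`` — natural cubic spline in d_t, the count of consecutive deep dives
  immediately before dive t;
* ``H`` — periodic cubic B-spline in the hour of day at dive initiation,
  with period 24 h (value and first two derivatives match at 0/24).

The diagonal predictors are pinned at eta_ii = 0 (reference coding) and
rows are mapped to probabilities by a softmax, so each row of the
transition probability matrix is strictly positive and sums to one.

Named presets ``model1``..``model4`` reproduce the standard 3-state term
structures (diurnal effects everywhere; tau effects out of the shallow
and medium states; deep-dive-count effects out of the deep state), and
generalise to other m by treating the deepest state's rows as the
D-carrying ones.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import BSpline

TERM_ORDER = ("T", "D", "H")


# ---------------------------------------------------------------------------
# spline bases

def _bspline_columns(x: np.ndarray, knots: np.ndarray, deriv: int = 0) -> np.ndarray:
    """Dense cubic B-spline design matrix (n x (len(knots)-4))."""
    nb = len(knots) - 4
    if deriv == 0:
        return BSpline.design_matrix(x, knots, 3, extrapolate=True).toarray()
    out = np.empty((len(x), nb))
    for j in range(nb):
        c = np.zeros(nb)
        c[j] = 1.0
        out[:, j] = BSpline(knots, c, 3, extrapolate=True).derivative(deriv)(x)
    return out


@dataclass
class NaturalSplineBasis:
    """Natural cubic spline basis (no intercept column).

    Constructed like R's ``ns()``: a cubic B-spline basis on the given
    knots, projected onto the subspace with vanishing second derivative
    at the boundary knots, with the intercept direction removed; the
    basis is linear beyond the boundary knots.  ``df`` equals
    ``len(interior_knots) + 1``.
    """

    interior_knots: np.ndarray
    boundary_knots: tuple[float, float]
    _proj: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self):
        self.interior_knots = np.sort(np.asarray(self.interior_knots, dtype=float))
        a, b = self.boundary_knots
        self.boundary_knots = (float(a), float(b))
        if self.degenerate:
            return
        if not (a < b):
            raise ValueError("boundary knots must satisfy a < b")
        if np.any(self.interior_knots < a) or np.any(self.interior_knots > b):
            raise ValueError("interior knots must lie within the boundary knots")
        self._all_knots = np.concatenate([[a] * 4, self.interior_knots, [b] * 4])
        # second-derivative values of each B-spline at the boundaries
        const = _bspline_columns(np.array([a, b]), self._all_knots, deriv=2)
        # drop the intercept column, then project out the two natural
        # constraints (QR null space), exactly as ns() does
        const = const[:, 1:]
        q, _ = np.linalg.qr(const.T, mode="complete")
        self._proj = q[:, 2:]

    @property
    def degenerate(self) -> bool:
        return self.boundary_knots[0] == self.boundary_knots[1]

    @property
    def df(self) -> int:
        return len(self.interior_knots) + 1

    @classmethod
    def from_data(cls, x, df: int = 3) -> "NaturalSplineBasis":
        """Quantile-based knots: interior at the k/df quantiles, boundary
        at the data range."""
        if df < 1:
            raise ValueError("df must be >= 1")
        x = np.asarray(x, dtype=float)
        if not np.all(np.isfinite(x)):
            raise ValueError("covariate values must be finite")
        lo, hi = float(np.min(x)), float(np.max(x))
        if lo == hi:
            warnings.warn("constant covariate: natural spline basis is degenerate")
            return cls(np.zeros(df - 1), (lo, hi))
        probs = np.arange(1, df) / df
        interior = np.quantile(x, probs)
        if len(np.unique(np.concatenate([[lo], interior, [hi]]))) < df + 1:
            # too few distinct values for distinct knots: spread them
            interior = lo + probs * (hi - lo)
        return cls(interior, (lo, hi))

    def design(self, x) -> np.ndarray:
        """Evaluate the basis at ``x``; linear extension outside the
        boundary knots."""
        x = np.atleast_1d(np.asarray(x, dtype=float))
        if self.degenerate:
            return np.zeros((len(x), self.df))
        a, b = self.boundary_knots
        inside = np.clip(x, a, b)
        base = _bspline_columns(inside, self._all_knots)[:, 1:] @ self._proj
        lo, hi = x < a, x > b
        if np.any(lo) or np.any(hi):
            for mask, bk in ((lo, a), (hi, b)):
                if not np.any(mask):
                    continue
                pt = np.array([bk])
                v0 = _bspline_columns(pt, self._all_knots)[:, 1:] @ self._proj
                v1 = _bspline_columns(pt, self._all_knots, deriv=1)[:, 1:] @ self._proj
                base[mask] = v0 + (x[mask, None] - bk) * v1
        return base


@dataclass
class PeriodicSplineBasis:
    """Periodic cubic B-spline basis on [0, period).

    Built from ``df + 1`` uniformly spaced wrapped cubic B-splines with
    the first one dropped, as periodic regression bases conventionally do
    so that the constant function is *not* in the span (the full wrapped
    set sums to one, which would alias the intercept).  Every basis
    function and its first two derivatives match at 0 and ``period``.
    """

    df: int = 3
    period: float = 24.0

    def __post_init__(self):
        if self.df < 1:
            raise ValueError("df must be >= 1")

    def _all_columns(self, h: np.ndarray) -> np.ndarray:
        nfun = self.df + 1
        step = self.period / nfun
        knots = np.arange(5) * step  # base cubic B-spline on [0, 4*step]
        base = BSpline.basis_element(knots, extrapolate=False)
        n_shift = int(np.ceil(4 * step / self.period)) + 1
        out = np.zeros((len(h), nfun))
        for j in range(nfun):
            for s in range(-1, n_shift + 1):
                u = h - j * step + s * self.period
                vals = base(u)
                out[:, j] += np.nan_to_num(vals, nan=0.0)
        return out

    def design(self, hours) -> np.ndarray:
        h = np.atleast_1d(np.asarray(hours, dtype=float))
        if np.any(h < 0) or np.any(h >= self.period):
            raise ValueError(f"hour values must lie in [0, {self.period})")
        return self._all_columns(h)[:, 1:]


# ---------------------------------------------------------------------------
# covariate model specification

_COV_OF_TERM = {"T": "tau_h", "D": "d_count", "H": "hour"}


@dataclass
class CovariateModel:
    """Term structure of the off-diagonal predictors.

    ``terms`` maps each ordered 1-based state pair (i, j), i != j, to a
    tuple drawn from {"T", "D", "H"}; every predictor always includes an
    intercept.  Spline bases for tau and d are frozen from the training
    covariates by :meth:`freeze`; the hour basis is fixed by the period.
    """

    m: int
    terms: dict
    df: int = 3
    tau_basis: NaturalSplineBasis | None = None
    d_basis: NaturalSplineBasis | None = None
    hour_basis: PeriodicSplineBasis | None = None
    name: str | None = None

    def __post_init__(self):
        pairs = self.pairs
        unknown = set(self.terms) - set(pairs)
        if unknown:
            raise ValueError(f"terms given for invalid state pairs {sorted(unknown)}")
        for p in pairs:
            bad = set(self.terms.get(p, ())) - set(TERM_ORDER)
            if bad:
                raise ValueError(f"unknown terms {sorted(bad)} for pair {p}")
        self.terms = {p: tuple(t for t in TERM_ORDER if t in self.terms.get(p, ()))
                      for p in pairs}
        if self.hour_basis is None:
            self.hour_basis = PeriodicSplineBasis(df=self.df)

    @property
    def pairs(self) -> list:
        return [(i, j) for i in range(1, self.m + 1)
                for j in range(1, self.m + 1) if i != j]

    @classmethod
    def preset(cls, name: str, m: int = 3, df: int = 3) -> "CovariateModel":
        """Named term structures model1..model4 (generalised to any m by
        giving the deepest state the deep-dive-count terms)."""
        name = name.lower()
        deep = m  # states are labelled shallow -> deep
        layouts = {
            "model1": lambda i, j: ("D", "H") if i == deep else ("T", "H"),
            "model2": lambda i, j: ("H",),
            "model3": lambda i, j: ("D", "H") if i == deep else ("T",),
            "model4": lambda i, j: ("D",) if i == deep else ("T",),
            "intercept": lambda i, j: (),
        }
        if name not in layouts:
            raise ValueError(f"unknown preset {name!r}")
        terms = {(i, j): layouts[name](i, j)
                 for i in range(1, m + 1) for j in range(1, m + 1) if i != j}
        return cls(m=m, terms=terms, df=df, name=name)

    @classmethod
    def from_config(cls, m: int, eta: dict, df: int = 3) -> "CovariateModel":
        """Build from a config mapping like ``{"1->2": ["intercept","T","H"]}``."""
        terms = {}
        for key, ts in eta.items():
            i, j = (int(s) for s in str(key).replace(" ", "").split("->"))
            terms[(i, j)] = tuple(t for t in ts if t != "intercept")
        return cls(m=m, terms=terms, df=df)

    def uses(self, term: str) -> bool:
        return any(term in ts for ts in self.terms.values())

    def n_coef(self, pair) -> int:
        return 1 + self.df * len(self.terms[pair])

    @property
    def n_params(self) -> int:
        return sum(self.n_coef(p) for p in self.pairs)

    def freeze(self, covariates) -> "CovariateModel":
        """Fix tau/d spline knots from training covariates (quantiles)."""
        if self.uses("T") and self.tau_basis is None:
            self.tau_basis = NaturalSplineBasis.from_data(
                np.asarray(covariates["tau_h"], dtype=float), df=self.df)
        if self.uses("D") and self.d_basis is None:
            self.d_basis = NaturalSplineBasis.from_data(
                np.asarray(covariates["d_count"], dtype=float), df=self.df)
        return self

    def coef_names(self) -> list:
        names = []
        for (i, j) in self.pairs:
            names.append(f"eta[{i}->{j}].intercept")
            for t in self.terms[(i, j)]:
                names += [f"eta[{i}->{j}].{t}{k + 1}" for k in range(self.df)]
        return names

    def permutation_invariant(self, perm) -> bool:
        """True if relabelling states by ``perm`` (0-based, new->old) maps
        the term structure onto itself."""
        inv = np.argsort(perm)
        for (i, j) in self.pairs:
            pi, pj = inv[i - 1] + 1, inv[j - 1] + 1
            if self.terms[(i, j)] != self.terms[(pi, pj)]:
                return False
        return True


def transition_matrix(eta: np.ndarray) -> np.ndarray:
    """Softmax link: omega_ij = exp(eta_ij) / sum_j exp(eta_ij).

    ``eta`` has shape (..., m, m) with zero diagonal; rows of the result
    are strictly positive and sum to one.  Computed with per-row max
    subtraction for overflow safety.
    """
    eta = np.asarray(eta, dtype=float)
    if not np.all(np.isfinite(eta)):
        raise ValueError("predictors must be finite")
    shifted = eta - eta.max(axis=-1, keepdims=True)
    w = np.exp(shifted)
    return w / w.sum(axis=-1, keepdims=True)


class TransitionDesign:
    """Per-pair design matrices for a covariate sequence, built once so
    that repeated likelihood evaluations only pay for dot products."""

    def __init__(self, model: CovariateModel, covariates):
        self.model = model
        tau = np.asarray(covariates["tau_h"], dtype=float)
        d = np.asarray(covariates["d_count"], dtype=float)
        hour = np.asarray(covariates["hour"], dtype=float)
        self.n = len(hour)
        bases = {}
        if model.uses("T"):
            if model.tau_basis is None:
                raise ValueError("tau spline basis not frozen; call model.freeze()")
            bases["T"] = model.tau_basis.design(tau)
        if model.uses("D"):
            if model.d_basis is None:
                raise ValueError("d spline basis not frozen; call model.freeze()")
            bases["D"] = model.d_basis.design(d)
        if model.uses("H"):
            bases["H"] = model.hour_basis.design(hour)
        ones = np.ones((self.n, 1))
        self.X = {}
        self.slices = {}
        offset = 0
        for pair in model.pairs:
            cols = [ones] + [bases[t] for t in model.terms[pair]]
            self.X[pair] = np.hstack(cols)
            k = self.X[pair].shape[1]
            self.slices[pair] = slice(offset, offset + k)
            offset += k
        self.n_params = offset

    def eta(self, beta: np.ndarray) -> np.ndarray:
        """Predictor array (n, m, m) with zero diagonal."""
        beta = np.asarray(beta, dtype=float)
        if beta.shape != (self.n_params,):
            raise ValueError(f"expected {self.n_params} transition coefficients")
        m = self.model.m
        eta = np.zeros((self.n, m, m))
        for (i, j), sl in self.slices.items():
            eta[:, i - 1, j - 1] = self.X[(i, j)] @ beta[sl]
        return eta

    def matrices(self, beta: np.ndarray) -> np.ndarray:
        """Row-stochastic transition matrices, shape (n, m, m)."""
        return transition_matrix(self.eta(beta))

    def score_from_eta_grad(self, deta: np.ndarray) -> np.ndarray:
        """Map d loglik / d eta (n, m, m) to the coefficient gradient."""
        g = np.empty(self.n_params)
        for (i, j), sl in self.slices.items():
            g[sl] = self.X[(i, j)].T @ deta[:, i - 1, j - 1]
        return g
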