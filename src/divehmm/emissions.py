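"""State-dependent distributions for the per-dive response triple.

Each hidden state carries a trivariate distribution for
``(MD, DT, PD)`` — maximum depth (m), dive duration (min) and post-dive
surface time (min).  Four families are supported:

``gamma_indep``
    Independent gamma marginals per coordinate, parametrised by shape
    ``mu`` and scale ``sigma`` (mean ``mu*sigma``, variance ``mu*sigma**2``).
``gamma_dep``
    The same gamma marginals tied together by a Gaussian copula; the
    dependence parameter ``rho`` is the copula correlation.
``lognormal_indep``
    log X multivariate normal with diagonal covariance; ``mu``/``sigma``
    are the log-mean and log-SD per coordinate.
``lognormal_dep``
    log X fully multivariate normal; ``rho`` holds log-scale correlations.

The default dependence structure couples MD and DT only (one ``rho`` per
state); a full 3x3 structure over all pairs is available via
``dependence="full"``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats
from scipy.special import gammaln, roots_hermitenorm

FAMILIES = ("gamma_indep", "gamma_dep", "lognormal_indep", "lognormal_dep")
COORDS = ("MD", "DT", "PD")
#: rho column order: pairs (MD,DT), (MD,PD), (DT,PD)
PAIRS = ((0, 1), (0, 2), (1, 2))


def _as_2d(x) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim == 1:
        x = x[None, :]
    if x.ndim != 2 or x.shape[1] != 3:
        raise ValueError("responses must have shape (n, 3): (MD, DT, PD)")
    return x


@dataclass
class EmissionParams:
    """Natural-scale emission parameters for all states.

    Parameters
    ----------
    family : str
        One of :data:`FAMILIES`.
    mu, sigma : ndarray, shape (m, 3)
        Per-state, per-coordinate parameters (gamma shape/scale, or
        log-normal log-mean/log-SD).
    rho : ndarray, shape (m, 3)
        Dependence parameters per state in pair order
        (MD,DT), (MD,PD), (DT,PD); ignored for independent families.
    dependence : {"md_dt", "full"}
        Which rho entries are free.  ``md_dt`` (default) uses only the
        first column, the other pairs are fixed at zero.
    """

    family: str
    mu: np.ndarray
    sigma: np.ndarray
    rho: np.ndarray | None = None
    dependence: str = "md_dt"

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        self.mu = np.atleast_2d(np.asarray(self.mu, dtype=float))
        self.sigma = np.atleast_2d(np.asarray(self.sigma, dtype=float))
        if self.mu.shape != self.sigma.shape or self.mu.shape[1] != 3:
            raise ValueError("mu and sigma must both have shape (m, 3)")
        m = self.mu.shape[0]
        if self.rho is None:
            self.rho = np.zeros((m, 3))
        else:
            rho = np.asarray(self.rho, dtype=float)
            if rho.ndim == 1:  # one MD-DT correlation per state
                full = np.zeros((m, 3))
                full[:, 0] = rho
                rho = full
            self.rho = rho
        if self.rho.shape != (m, 3):
            raise ValueError("rho must have shape (m,) or (m, 3)")
        if self.dependence not in ("md_dt", "full"):
            raise ValueError("dependence must be 'md_dt' or 'full'")
        if not self.is_dependent:
            self.rho = np.zeros((m, 3))
        elif self.dependence == "md_dt":
            self.rho[:, 1:] = 0.0
        self._validate()

    def _validate(self):
        if self.family.startswith("gamma") and not np.all(self.mu > 0):
            raise ValueError("gamma shape parameters must be positive")
        if not np.all(self.sigma > 0):
            raise ValueError("scale/log-SD parameters must be positive")
        if not np.all(np.abs(self.rho) < 1):
            raise ValueError("correlations must lie in (-1, 1)")
        if self.dependence == "full":
            for i in range(self.n_states):
                if np.linalg.eigvalsh(self.corr_matrix(i)).min() <= 0:
                    raise ValueError(f"state {i + 1}: correlation matrix not PD")

    @property
    def n_states(self) -> int:
        return self.mu.shape[0]

    @property
    def is_dependent(self) -> bool:
        return self.family.endswith("_dep")

    @property
    def n_rho(self) -> int:
        """Free dependence parameters per state."""
        if not self.is_dependent:
            return 0
        return 1 if self.dependence == "md_dt" else 3

    def corr_matrix(self, state: int) -> np.ndarray:
        """3x3 correlation matrix of state ``state`` (0-based)."""
        r = np.eye(3)
        for col, (a, b) in enumerate(PAIRS):
            r[a, b] = r[b, a] = self.rho[state, col]
        return r

    def cov_matrix(self, state: int) -> np.ndarray:
        """Log-scale covariance Sigma_i (log-normal families)."""
        s = self.sigma[state]
        return self.corr_matrix(state) * np.outer(s, s)

    def permute_states(self, perm) -> "EmissionParams":
        """Reorder states so that new state k is old state ``perm[k]``."""
        perm = np.asarray(perm)
        return replace(self, mu=self.mu[perm].copy(), sigma=self.sigma[perm].copy(),
                       rho=self.rho[perm].copy())


# ---------------------------------------------------------------------------
# densities

def _gamma_marginal_logpdf(x: np.ndarray, mu: np.ndarray, sigma: np.ndarray) -> np.ndarray:
    # shape mu, scale sigma; x broadcast against (m, 3) parameters
    return (-gammaln(mu) - mu * np.log(sigma)
            + (mu - 1.0) * np.log(x) - x / sigma)


def log_density(x, params: EmissionParams, state: int | None = None) -> np.ndarray:
    """Log state-dependent density of response triples.

    Parameters
    ----------
    x : array-like, shape (n, 3) or (3,)
        Strictly positive (MD, DT, PD) values.
    state : int, optional
        0-based state index.  If omitted, densities for all states are
        returned with shape (n, m).

    Returns
    -------
    ndarray, shape (n,) or (n, m)
    """
    x = _as_2d(x)
    if not np.all(x > 0):
        raise ValueError("all response coordinates must be strictly positive")
    m = params.n_states
    states = range(m) if state is None else [state]
    out = np.empty((x.shape[0], len(states)))
    logx = np.log(x)
    for col, i in enumerate(states):
        if params.family.startswith("gamma"):
            lp = _gamma_marginal_logpdf(x, params.mu[i], params.sigma[i]).sum(axis=1)
            if params.family == "gamma_dep":
                lp = lp + _gauss_copula_logdens(x, params, i)
        else:
            cov = params.cov_matrix(i)
            try:
                chol = np.linalg.cholesky(cov)
            except np.linalg.LinAlgError:
                raise ValueError(f"state {i + 1}: log-scale covariance not PD")
            dev = np.linalg.solve(chol, (logx - params.mu[i]).T)
            quad = np.sum(dev * dev, axis=0)
            logdet = 2.0 * np.sum(np.log(np.diag(chol)))
            lp = (-0.5 * (3 * np.log(2 * np.pi) + logdet + quad)
                  - logx.sum(axis=1))
        out[:, col] = lp
    return out[:, 0] if state is not None else out


def _gauss_copula_logdens(x: np.ndarray, params: EmissionParams, i: int) -> np.ndarray:
    """Gaussian-copula log-density factor for the dependent gamma family."""
    u = stats.gamma.cdf(x, a=params.mu[i], scale=params.sigma[i])
    u = np.clip(u, 1e-14, 1 - 1e-14)
    z = stats.norm.ppf(u)
    corr = params.corr_matrix(i)
    inv = np.linalg.inv(corr)
    _, logdet = np.linalg.slogdet(corr)
    quad = np.einsum("nj,jk,nk->n", z, inv - np.eye(3), z)
    return -0.5 * (logdet + quad)


# ---------------------------------------------------------------------------
# moments

def lognormal_response_correlation(rho: float, s1: float, s2: float) -> float:
    """Response-scale correlation implied by a log-scale correlation.

    ``(exp(rho*s1*s2) - 1) / sqrt((exp(s1^2) - 1)(exp(s2^2) - 1))`` for
    log-SDs ``s1``, ``s2``.
    """
    return (np.exp(rho * s1 * s2) - 1.0) / np.sqrt(
        np.expm1(s1 ** 2) * np.expm1(s2 ** 2))


def lognormal_log_correlation(r: float, s1: float, s2: float) -> float:
    """Invert :func:`lognormal_response_correlation` for a target corr ``r``."""
    return np.log1p(r * np.sqrt(np.expm1(s1 ** 2) * np.expm1(s2 ** 2))) / (s1 * s2)


def _copula_gamma_corr(rho: float, mu: np.ndarray, sigma: np.ndarray,
                       n_nodes: int = 48) -> float:
    """Response-scale MD-DT correlation of the copula-gamma pair.

    No closed form exists; E[X1 X2] is computed by Gauss-Hermite
    quadrature over the latent bivariate normal.
    """
    nodes, weights = roots_hermitenorm(n_nodes)
    w = weights / weights.sum()
    z1 = nodes[:, None]
    z2 = rho * z1 + np.sqrt(1 - rho ** 2) * nodes[None, :]
    q1 = stats.gamma.ppf(np.clip(stats.norm.cdf(z1), 1e-14, 1 - 1e-14),
                         a=mu[0], scale=sigma[0])
    q2 = stats.gamma.ppf(np.clip(stats.norm.cdf(z2), 1e-14, 1 - 1e-14),
                         a=mu[1], scale=sigma[1])
    exy = float(np.einsum("i,ij,j->", w, q1 * q2, w))
    mean = mu[:2] * sigma[:2]
    sd = np.sqrt(mu[:2]) * sigma[:2]
    return (exy - mean[0] * mean[1]) / (sd[0] * sd[1])


def moments(params: EmissionParams, state: int) -> dict:
    """Closed-form response-scale mean/SD per coordinate and MD-DT correlation.

    Returns a dict with keys ``mean``, ``sd`` (length-3 arrays in MD, DT,
    PD order) and ``corr_md_dt``.
    """
    i = state
    if params.family.startswith("gamma"):
        mean = params.mu[i] * params.sigma[i]
        sd = np.sqrt(params.mu[i]) * params.sigma[i]
        corr = 0.0
        if params.family == "gamma_dep" and params.rho[i, 0] != 0.0:
            corr = _copula_gamma_corr(params.rho[i, 0], params.mu[i], params.sigma[i])
    else:
        s2 = params.sigma[i] ** 2
        mean = np.exp(params.mu[i] + s2 / 2)
        sd = np.sqrt(np.expm1(s2)) * np.exp(params.mu[i] + s2 / 2)
        corr = lognormal_response_correlation(
            params.rho[i, 0], params.sigma[i, 0], params.sigma[i, 1])
    return {"mean": mean, "sd": sd, "corr_md_dt": float(corr)}


# ---------------------------------------------------------------------------
# sampling

def sample(state: int, params: EmissionParams, n: int,
           rng: np.random.Generator | int | None = None) -> np.ndarray:
    """Draw ``n`` response triples from state ``state`` (0-based)."""
    rng = np.random.default_rng(rng)
    if n == 0:
        return np.empty((0, 3))
    i = state
    corr = params.corr_matrix(i)
    if params.family.startswith("lognormal"):
        y = rng.multivariate_normal(params.mu[i], params.cov_matrix(i), size=n)
        return np.exp(y)
    if params.family == "gamma_dep" and params.n_rho:
        z = rng.multivariate_normal(np.zeros(3), corr, size=n)
        u = np.clip(stats.norm.cdf(z), 1e-14, 1 - 1e-14)
        return stats.gamma.ppf(u, a=params.mu[i], scale=params.sigma[i])
    return rng.gamma(shape=params.mu[i], scale=params.sigma[i], size=(n, 3))


# ---------------------------------------------------------------------------
# working-parameter transforms

def _corr_to_partial(r: np.ndarray) -> np.ndarray:
    """(r12, r13, r23) -> canonical partial correlations (p12, p13, p23.1).

    The partials are variation-independent in (-1, 1)^3, so elementwise
    artanh gives an unconstrained parametrisation of PD correlation
    matrices.
    """
    r12, r13, r23 = r
    p23 = (r23 - r12 * r13) / np.sqrt((1 - r12 ** 2) * (1 - r13 ** 2))
    return np.array([r12, r13, p23])


def _partial_to_corr(p: np.ndarray) -> np.ndarray:
    p12, p13, p23 = p
    r23 = p23 * np.sqrt((1 - p12 ** 2) * (1 - p13 ** 2)) + p12 * p13
    return np.array([p12, p13, r23])


def n_working(family: str, m: int, dependence: str = "md_dt") -> int:
    base = 6 * m
    if family.endswith("_dep"):
        base += (1 if dependence == "md_dt" else 3) * m
    return base


def to_working(params: EmissionParams) -> np.ndarray:
    """Map natural parameters to an unconstrained vector.

    Positive parameters go through log, correlations through artanh;
    log-normal log-means are already unconstrained.  Layout per state:
    mu (3), sigma (3), then the free rho entries.
    """
    blocks = []
    lognormal = params.family.startswith("lognormal")
    for i in range(params.n_states):
        mu = params.mu[i] if lognormal else np.log(params.mu[i])
        blocks += [mu, np.log(params.sigma[i])]
        if params.n_rho == 1:
            blocks.append(np.arctanh(params.rho[i, :1]))
        elif params.n_rho == 3:
            blocks.append(np.arctanh(_corr_to_partial(params.rho[i])))
    return np.concatenate(blocks)


def from_working(vec: np.ndarray, family: str, m: int,
                 dependence: str = "md_dt") -> EmissionParams:
    """Inverse of :func:`to_working`."""
    vec = np.asarray(vec, dtype=float)
    expected = n_working(family, m, dependence)
    if vec.shape != (expected,):
        raise ValueError(f"expected working vector of length {expected}, got {vec.shape}")
    dep = family.endswith("_dep")
    k = (1 if dependence == "md_dt" else 3) if dep else 0
    per = 6 + k
    mu = np.empty((m, 3))
    sigma = np.empty((m, 3))
    rho = np.zeros((m, 3))
    for i in range(m):
        b = vec[i * per:(i + 1) * per]
        mu[i] = b[:3] if family.startswith("lognormal") else np.exp(b[:3])
        sigma[i] = np.exp(b[3:6])
        if k == 1:
            rho[i, 0] = np.tanh(b[6])
        elif k == 3:
            rho[i] = _partial_to_corr(np.tanh(b[6:9]))
    return EmissionParams(family=family, mu=mu, sigma=sigma, rho=rho,
                          dependence=dependence if dep else "md_dt")
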