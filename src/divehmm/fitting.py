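"""Maximum-likelihood estimation of dive HMMs.

Estimation is by direct numerical optimisation of the scaled-forward
log-likelihood on an unconstrained working scale (log for positive
parameters, artanh for correlations, free reals for predictor
coefficients), with a multi-start protocol: emission starts come from a
univariate mixture fit to the maximum depths, the MD-DT dependence
parameter starts at the empirical log-scale correlation, and transition
intercepts are drawn from an integer grid in [-5, 5] with seeded jitter.

For the log-normal families the score is computed analytically from the
forward-backward posteriors (state posteriors drive the emission block,
transition-pair posteriors drive the softmax coefficients), which makes
the quasi-Newton iterations cheap; the gamma families use
finite-difference gradients.

Confidence intervals are Wald intervals from the Hessian of the negative
log-likelihood (observed Fisher information) on the working scale, mapped
through the monotone back-transforms to the natural scale.
"""

from __future__ import annotations

import hashlib
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from sklearn.mixture import GaussianMixture
from statsmodels.tools import numdiff

from . import emissions as em
from . import _kernels, hmm_core
from .hmm_core import HMMParams, HMMSpec, responses
from .transitions import TransitionDesign

logger = logging.getLogger(__name__)

_BIG = 1e12


# ---------------------------------------------------------------------------
# parameter bookkeeping

def count_parameters(spec: HMMSpec) -> int:
    """Total free parameters: per state 3 means + 3 scales (+ dependence
    parameters), plus one intercept and df coefficients per spline term
    for every off-diagonal predictor."""
    return em.n_working(spec.family, spec.m, spec.dependence) + \
        spec.covariate_model.n_params


def split_working(theta: np.ndarray, spec: HMMSpec):
    k = em.n_working(spec.family, spec.m, spec.dependence)
    return theta[:k], theta[k:]


def pack_params(params: HMMParams, spec: HMMSpec) -> np.ndarray:
    return np.concatenate([em.to_working(params.emission), params.beta])


def unpack_params(theta: np.ndarray, spec: HMMSpec) -> HMMParams:
    w_em, beta = split_working(theta, spec)
    return HMMParams(emission=em.from_working(w_em, spec.family, spec.m,
                                              spec.dependence),
                     beta=beta.copy())


def param_labels(spec: HMMSpec) -> list:
    labels = []
    coords = em.COORDS
    n_rho = (1 if spec.dependence == "md_dt" else 3) if spec.family.endswith("_dep") else 0
    pair_names = ["MD:DT", "MD:PD", "DT:PD"]
    for i in range(1, spec.m + 1):
        labels += [f"mu[{i},{k}]" for k in coords]
        labels += [f"sigma[{i},{k}]" for k in coords]
        labels += [f"rho[{i},{pair_names[r]}]" for r in range(n_rho)]
    return labels + spec.covariate_model.coef_names()


def _natural_codes(spec: HMMSpec) -> list:
    """Back-transform code per working coordinate: id, exp or tanh."""
    mu_code = "id" if spec.family.startswith("lognormal") else "exp"
    n_rho = (1 if spec.dependence == "md_dt" else 3) if spec.family.endswith("_dep") else 0
    codes = ([mu_code] * 3 + ["exp"] * 3 + ["tanh"] * n_rho) * spec.m
    return codes + ["id"] * spec.covariate_model.n_params

_TRANSFORMS = {"id": lambda v: v, "exp": np.exp, "tanh": np.tanh}


# ---------------------------------------------------------------------------
# objective

class _Objective:
    """Negative log-likelihood (and score, for log-normal families) as a
    function of the working parameter vector, with frozen designs."""

    def __init__(self, x: np.ndarray, design: TransitionDesign, spec: HMMSpec):
        self.x = x
        self.logx = np.log(x)
        self.design = design
        self.spec = spec
        # the analytic score assumes the elementwise working transforms of
        # the md_dt dependence structure; other cases use finite differences
        self.analytic = (spec.family.startswith("lognormal")
                         and (spec.dependence == "md_dt"
                              or not spec.family.endswith("_dep")))

    def _pieces(self, theta):
        p = unpack_params(theta, self.spec)
        logf = em.log_density(self.x, p.emission)
        Gamma_full = self.design.matrices(p.beta)
        return p, logf, Gamma_full

    def value(self, theta) -> float:
        try:
            _, logf, Gf = self._pieces(theta)
        except (ValueError, FloatingPointError, np.linalg.LinAlgError):
            return _BIG
        if not np.all(np.isfinite(logf)):
            return _BIG
        ll = _kernels.forward_loglik(logf, Gf[:-1], self.spec.delta)
        return -ll if np.isfinite(ll) else _BIG

    def value_and_grad(self, theta):
        spec = self.spec
        try:
            p, logf, Gf = self._pieces(theta)
        except (ValueError, FloatingPointError, np.linalg.LinAlgError):
            return _BIG, np.zeros_like(theta)
        if not np.all(np.isfinite(logf)):
            return _BIG, np.zeros_like(theta)
        T, m = logf.shape
        ll, post, xi = _kernels.forward_backward(logf, Gf[:-1], spec.delta)
        if not np.isfinite(ll):
            return _BIG, np.zeros_like(theta)
        pe = p.emission
        y = self.logx
        n_rho = pe.n_rho
        g_em = []
        for i in range(m):
            w = post[:, i]
            W = w.sum()
            Sigma = pe.cov_matrix(i)
            Sinv = np.linalg.inv(Sigma)
            dev = y - pe.mu[i]
            S1 = w @ dev                      # sum w_t (y_t - mu)
            M = (dev * w[:, None]).T @ dev    # sum w_t (y_t-mu)(y_t-mu)^T
            g_mu = Sinv @ S1
            G = 0.5 * (Sinv @ M @ Sinv - W * Sinv)
            R = pe.corr_matrix(i)
            sig = pe.sigma[i]
            g_sigma = 2.0 * np.einsum("kb,kb,b->k", G, R, sig)
            block = [g_mu, g_sigma * sig]     # chain: d sigma / d log sigma
            if n_rho:
                g_rho = np.array([2.0 * G[a, b] * sig[a] * sig[b]
                                  for (a, b) in em.PAIRS[:n_rho]])
                block.append(g_rho * (1.0 - pe.rho[i, :n_rho] ** 2))
            g_em.append(np.concatenate(block))
        # transition block: d ll / d eta[t,i,k] = xi[t,i,k] - Gamma[t,i,k] post[t,i]
        deta = np.zeros((T, m, m))
        if T > 1:
            deta[:-1] = xi - Gf[:-1] * post[:-1, :, None]
        g_beta = self.design.score_from_eta_grad(deta)
        grad = np.concatenate(g_em + [g_beta])
        return -ll, -grad


# ---------------------------------------------------------------------------
# starting values

def _quantile_groups(md: np.ndarray, m: int) -> np.ndarray:
    """Fallback grouping: slice dives into m equal-count bands of MD."""
    order = np.argsort(md, kind="stable")
    groups = np.empty(len(md), dtype=int)
    for g, chunk in enumerate(np.array_split(order, m)):
        groups[chunk] = g
    return groups


def _mixture_groups(md: np.ndarray, m: int, seed: int) -> np.ndarray:
    gm = GaussianMixture(n_components=m, n_init=3, random_state=seed & 0x7FFFFFFF)
    labels = gm.fit_predict(np.log(md)[:, None])
    order = np.argsort(gm.means_.ravel())
    relabel = np.empty(m, dtype=int)
    relabel[order] = np.arange(m)
    return relabel[labels]


def _moment_start(x: np.ndarray, groups: np.ndarray, spec: HMMSpec) -> em.EmissionParams:
    m = spec.m
    mu = np.empty((m, 3))
    sigma = np.empty((m, 3))
    lognormal = spec.family.startswith("lognormal")
    for g in range(m):
        xi = x[groups == g]
        if lognormal:
            mu[g] = np.log(xi).mean(axis=0)
            sigma[g] = np.maximum(np.log(xi).std(axis=0), 1e-3)
        else:
            mean = xi.mean(axis=0)
            sd = np.maximum(xi.std(axis=0), 1e-6)
            mu[g] = (mean / sd) ** 2
            sigma[g] = sd ** 2 / mean
    rho = np.zeros((m, 3))
    if spec.family.endswith("_dep"):
        r = np.corrcoef(np.log(x[:, 0]), np.log(x[:, 1]))[0, 1]
        rho[:, 0] = np.clip(r, -0.95, 0.95)
    return em.EmissionParams(family=spec.family, mu=mu, sigma=sigma, rho=rho,
                             dependence=spec.dependence)


def initial_values(dives, spec: HMMSpec, n_starts: int = 1, seed: int = 0,
                   jitter: float = 0.1) -> list:
    """Working-scale starting vectors.

    Start 0 is deterministic: mixture-based emission parameters (states
    sorted by mean MD), MD-DT correlation at its empirical log-scale
    value, all transition coefficients zero.  Later starts jitter the
    emission block and draw each predictor intercept from the integer
    grid {-5, ..., 5}.
    """
    if n_starts < 1:
        raise ValueError("n_starts must be >= 1")
    x = responses(dives)
    m = spec.m
    try:
        groups = _mixture_groups(x[:, 0], m, seed) if m > 1 else np.zeros(len(x), dtype=int)
        if np.bincount(groups, minlength=m).min() < 3:
            raise ValueError("mixture produced a near-empty component")
        base_em = _moment_start(x, groups, spec)
    except Exception as exc:  # mixture failure -> quantile slices
        logger.warning("mixture initialisation failed (%s); using quantile slices", exc)
        groups = _quantile_groups(x[:, 0], m)
        base_em = _moment_start(x, groups, spec)
    w_em = em.to_working(base_em)
    n_beta = spec.covariate_model.n_params
    starts = [np.concatenate([w_em, np.zeros(n_beta)])]
    rng = np.random.default_rng(seed)
    grid = np.arange(-5, 6, dtype=float)
    intercept_cols = [sl.start for sl in
                      _beta_slices(spec.covariate_model).values()]
    for _ in range(n_starts - 1):
        v = starts[0].copy()
        v[:len(w_em)] += rng.normal(0.0, jitter, size=len(w_em))
        beta = np.zeros(n_beta)
        for c in intercept_cols:
            beta[c] = rng.choice(grid) + rng.normal(0.0, jitter)
        v[len(w_em):] = beta
        starts.append(v)
    return starts


def _beta_slices(model):
    out, offset = {}, 0
    for pair in model.pairs:
        k = model.n_coef(pair)
        out[pair] = slice(offset, offset + k)
        offset += k
    return out


# ---------------------------------------------------------------------------
# fit

@dataclass
class FitResult:
    """Outcome of a multi-start ML fit."""

    spec: HMMSpec
    params: HMMParams
    working: np.ndarray
    llf: float
    n_params: int
    aic: float
    se_working: np.ndarray | None
    conf_int: pd.DataFrame | None
    labels: list
    starts: pd.DataFrame
    best_start: int
    relabel_perm: np.ndarray | None
    decoded: np.ndarray
    degenerate_states: list
    data_hash: str
    ci_available: bool = True

    def moments_table(self) -> pd.DataFrame:
        """Response-scale mean/SD per state and the MD-DT correlation."""
        rows = {}
        for i in range(self.spec.m):
            mo = em.moments(self.params.emission, i)
            col = {}
            for k, c in enumerate(em.COORDS):
                col[f"E_{c}"] = mo["mean"][k]
                col[f"SD_{c}"] = mo["sd"][k]
            col["Corr_MD_DT"] = mo["corr_md_dt"]
            rows[f"state {i + 1}"] = col
        return pd.DataFrame(rows)


def _relabel(theta, spec: HMMSpec, design: TransitionDesign):
    """Sort states by ascending fitted mean MD where the covariate term
    structure allows it."""
    params = unpack_params(theta, spec)
    means = np.array([em.moments(params.emission, i)["mean"][0]
                      for i in range(spec.m)])
    perm = np.argsort(means, kind="stable")
    if np.array_equal(perm, np.arange(spec.m)):
        return theta, perm
    model = spec.covariate_model
    if not model.permutation_invariant(perm):
        warnings.warn("fitted state order violates the covariate term structure; "
                      "labels kept as fitted (not sorted by mean MD)")
        return theta, None
    new_em = params.emission.permute_states(perm)
    slices = _beta_slices(model)
    new_beta = np.empty_like(params.beta)
    for (i, j), sl in slices.items():
        src = (perm[i - 1] + 1, perm[j - 1] + 1)
        new_beta[sl] = params.beta[slices[src]]
    new_theta = np.concatenate([em.to_working(new_em), new_beta])
    return new_theta, perm


def _hessian(obj: _Objective, theta: np.ndarray) -> np.ndarray:
    if obj.analytic:
        grad = lambda th: obj.value_and_grad(th)[1]
        H = numdiff.approx_fprime(theta, grad, centered=True)
        return 0.5 * (H + H.T)
    return numdiff.approx_hess(theta, obj.value)


def confidence_intervals(theta, spec: HMMSpec, cov: np.ndarray,
                         level: float = 0.95) -> pd.DataFrame:
    """Wald intervals on the working scale mapped through the monotone
    back-transforms to the natural scale."""
    se = np.sqrt(np.diag(cov))
    z = stats.norm.ppf(0.5 + level / 2.0)
    lo_w, hi_w = theta - z * se, theta + z * se
    codes = _natural_codes(spec)
    est = np.array([_TRANSFORMS[c](v) for c, v in zip(codes, theta)])
    lo = np.array([_TRANSFORMS[c](v) for c, v in zip(codes, lo_w)])
    hi = np.array([_TRANSFORMS[c](v) for c, v in zip(codes, hi_w)])
    return pd.DataFrame({"estimate": est, "lower": np.minimum(lo, hi),
                         "upper": np.maximum(lo, hi), "se_working": se},
                        index=param_labels(spec))


def fit(dives, covariates, spec: HMMSpec, n_starts: int = 50, seed: int = 0,
        maxiter: int = 1000, ftol: float = 1e-8, gtol: float = 1e-5,
        compute_ci: bool = True, decode: bool = True) -> FitResult:
    """Multi-start maximum-likelihood fit.

    Spline knots of the covariate model are frozen from ``covariates`` if
    not already set.  States are relabelled by ascending fitted mean MD.
    """
    x = responses(dives)
    spec.covariate_model.freeze(covariates)
    design = TransitionDesign(spec.covariate_model, covariates)
    if design.n != len(x):
        raise ValueError("covariates not aligned with dives")
    npar = count_parameters(spec)
    if len(x) < 10 * npar:
        warnings.warn(f"T = {len(x)} is small for {npar} parameters "
                      "(fewer than 10 observations per parameter)")
    obj = _Objective(x, design, spec)
    starts = initial_values(dives, spec, n_starts=n_starts, seed=seed)

    rows, solutions = [], []
    for k, theta0 in enumerate(starts):
        if obj.analytic:
            res = optimize.minimize(obj.value_and_grad, theta0, jac=True,
                                    method="L-BFGS-B",
                                    options={"maxiter": maxiter, "ftol": ftol,
                                             "gtol": gtol})
        else:
            res = optimize.minimize(obj.value, theta0, method="L-BFGS-B",
                                    options={"maxiter": maxiter, "ftol": ftol,
                                             "gtol": gtol})
        ok = bool(res.success) and res.fun < _BIG / 2
        logger.info("start %d: ll = %.4f, converged = %s", k, -res.fun, ok)
        rows.append({"start": k, "llf": -res.fun, "converged": ok,
                     "n_iter": int(res.nit), "message": str(res.message)})
        solutions.append(res.x if res.fun < _BIG / 2 else None)
    starts_df = pd.DataFrame(rows)
    if not any(s is not None for s in solutions):
        raise RuntimeError(f"all {n_starts} optimisation starts failed:\n{starts_df}")
    usable = starts_df[[s is not None for s in solutions]]
    best = int(usable.loc[usable["llf"].idxmax(), "start"])
    theta = solutions[best]
    llf = float(starts_df.loc[best, "llf"])

    theta, perm = _relabel(theta, spec, design)
    params = unpack_params(theta, spec)

    se = None
    ci = None
    ci_ok = False
    if compute_ci:
        try:
            H = _hessian(obj, theta)
            evals = np.linalg.eigvalsh(H)
            if evals.min() <= 0 or not np.all(np.isfinite(H)):
                raise np.linalg.LinAlgError("Hessian not positive definite")
            cov = np.linalg.inv(H)
            se = np.sqrt(np.diag(cov))
            ci = confidence_intervals(theta, spec, cov)
            ci_ok = True
        except np.linalg.LinAlgError as exc:
            warnings.warn(f"confidence intervals unavailable: {exc}")

    decoded = (hmm_core.viterbi(x, covariates, spec, params, design)
               if decode else np.empty(0, dtype=int))
    degenerate = []
    if decode and len(decoded):
        share = np.bincount(decoded - 1, minlength=spec.m) / len(decoded)
        degenerate = [i + 1 for i in range(spec.m) if share[i] < 0.01]
        if degenerate:
            warnings.warn(f"states {degenerate} receive < 1% of decoded dives; "
                          "possible overfitting")

    return FitResult(spec=spec, params=params, working=theta, llf=llf,
                     n_params=npar, aic=-2.0 * llf + 2.0 * npar,
                     se_working=se, conf_int=ci, labels=param_labels(spec),
                     starts=starts_df, best_start=best, relabel_perm=perm,
                     decoded=decoded, degenerate_states=degenerate,
                     data_hash=hashlib.sha1(x.tobytes()).hexdigest(),
                     ci_available=ci_ok)


def aic_table(fits: list) -> pd.DataFrame:
    """Ranked AIC comparison (ascending dAIC); all fits must share the data."""
    if not fits:
        raise ValueError("no fits given")
    hashes = {f.data_hash for f in fits}
    if len(hashes) > 1:
        raise ValueError("AIC comparison requires fits on identical data")
    rows = [{"family": f.spec.family,
             "covariate_model": f.spec.covariate_model.name or "custom",
             "m": f.spec.m, "np": f.n_params, "llf": f.llf, "AIC": f.aic}
            for f in fits]
    tab = pd.DataFrame(rows).sort_values("AIC", kind="stable").reset_index(drop=True)
    tab["dAIC"] = tab["AIC"] - tab["AIC"].min()
    return tab
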