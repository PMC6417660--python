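"""Forward likelihood, Viterbi decoding and forecast pseudo-residuals.

The likelihood follows the matrix-product form

    L_T = delta P(x_1) Omega(tau_1, d_1, h_1) P(x_2) ... Omega(tau_{T-1}, ...) P(x_T) 1,

i.e. the transition from dive t into dive t+1 is governed by the
covariates of the *origin* dive t.  The initial distribution delta is
uniform by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import emissions as em
from . import _kernels
from .transitions import CovariateModel, TransitionDesign

RESPONSE_COLUMNS = ("MaxDepth", "Duration", "PostDiveDur")


@dataclass
class HMMSpec:
    """Structural description of a dive HMM: number of states, emission
    family/dependence and the covariate model of the transition
    probabilities."""

    m: int
    family: str
    covariate_model: CovariateModel
    dependence: str = "md_dt"
    delta: np.ndarray | None = None

    def __post_init__(self):
        if self.m < 1:
            raise ValueError("m must be >= 1")
        if self.family not in em.FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        if self.covariate_model.m != self.m:
            raise ValueError("covariate model built for a different number of states")
        if self.delta is None:
            self.delta = np.full(self.m, 1.0 / self.m)
        else:
            self.delta = np.asarray(self.delta, dtype=float)
            if self.delta.shape != (self.m,) or np.any(self.delta < 0):
                raise ValueError("delta must be a non-negative vector of length m")
            self.delta = self.delta / self.delta.sum()


@dataclass
class HMMParams:
    """Emission parameters plus the flat transition-coefficient vector."""

    emission: em.EmissionParams
    beta: np.ndarray

    def __post_init__(self):
        self.beta = np.asarray(self.beta, dtype=float)
        if not np.all(np.isfinite(self.beta)):
            raise ValueError("transition coefficients must be finite")


def responses(dives) -> np.ndarray:
    """(T, 3) response array (MD, DT, PD) from a dive table."""
    if isinstance(dives, pd.DataFrame):
        x = dives.loc[:, list(RESPONSE_COLUMNS)].to_numpy(dtype=float)
    else:
        x = np.asarray(dives, dtype=float)
    if x.ndim != 2 or x.shape[1] != 3:
        raise ValueError("dives must provide (MD, DT, PD) columns")
    if not np.all(x > 0):
        raise ValueError("non-positive response value in dive table")
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite response value in dive table")
    return x


def _parts(dives, covariates, spec: HMMSpec, params: HMMParams,
           design: TransitionDesign | None = None):
    x = responses(dives)
    logf = em.log_density(x, params.emission)
    if design is None:
        design = TransitionDesign(spec.covariate_model, covariates)
    if design.n != len(x):
        raise ValueError("covariates not aligned with dives")
    Gamma = design.matrices(params.beta)[:-1] if len(x) > 1 else \
        np.empty((0, spec.m, spec.m))
    return x, logf, Gamma, design


def log_likelihood(dives, covariates, spec: HMMSpec, params: HMMParams,
                   design: TransitionDesign | None = None) -> float:
    """Scaled-forward log-likelihood, O(T m^2)."""
    _, logf, Gamma, _ = _parts(dives, covariates, spec, params, design)
    return float(_kernels.forward_loglik(logf, Gamma, spec.delta))


def viterbi(dives, covariates, spec: HMMSpec, params: HMMParams,
            design: TransitionDesign | None = None) -> np.ndarray:
    """Most probable state path, 1-based labels; ties go to the lowest
    state index."""
    _, logf, Gamma, _ = _parts(dives, covariates, spec, params, design)
    tiny = 1e-300
    return np.asarray(_kernels.viterbi_path(
        logf, np.log(Gamma + tiny), np.log(spec.delta + tiny))) + 1


def state_posteriors(dives, covariates, spec: HMMSpec, params: HMMParams,
                     design: TransitionDesign | None = None):
    """(loglik, P(C_t = i | all data)) via forward-backward."""
    _, logf, Gamma, _ = _parts(dives, covariates, spec, params, design)
    ll, post, _ = _kernels.forward_backward(logf, Gamma, spec.delta)
    return float(ll), post


def _marginal_cdfs(x: np.ndarray, p: em.EmissionParams) -> np.ndarray:
    """Per-coordinate state-conditional CDFs, shape (T, m, 3).

    For the dependent families the univariate marginals are unchanged
    (log-normal marginals of the multivariate log-normal; gamma marginals
    of the copula construction), so no conditioning on sibling
    coordinates is involved.
    """
    T = x.shape[0]
    out = np.empty((T, p.n_states, 3))
    for i in range(p.n_states):
        if p.family.startswith("gamma"):
            out[:, i, :] = stats.gamma.cdf(x, a=p.mu[i], scale=p.sigma[i])
        else:
            out[:, i, :] = stats.norm.cdf(
                (np.log(x) - p.mu[i]) / p.sigma[i])
    return out


def pseudo_residuals(dives, covariates, spec: HMMSpec, params: HMMParams,
                     design: TransitionDesign | None = None) -> pd.DataFrame:
    """Forecast pseudo-residuals z_{t,k} = Phi^{-1}(P(X_{t,k} <= x_{t,k} | past)).

    The forecast distribution mixes the state-conditional marginal CDFs
    with the one-step-ahead state probabilities (delta for the first
    dive).  Under a correctly specified model the residuals are standard
    normal.
    """
    x, logf, Gamma, _ = _parts(dives, covariates, spec, params, design)
    P = np.asarray(_kernels.predictive_probs(logf, Gamma, spec.delta))
    cdfs = _marginal_cdfs(x, params.emission)
    u = np.einsum("ti,tik->tk", P, cdfs)
    z = stats.norm.ppf(np.clip(u, 1e-14, 1 - 1e-14))
    idx = dives.index if isinstance(dives, pd.DataFrame) else None
    return pd.DataFrame(z, columns=["z_MD", "z_DT", "z_PD"], index=idx)
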