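"""Model/Results objects — the user-facing API.

``DiveHMM`` is built from a dive-summary table (and optionally
pre-computed covariates); ``fit()`` returns a ``DiveHMMResults`` carrying
the estimates, Hessian-based confidence intervals, AIC, decoded states
and diagnostics, in the style of statsmodels.

Example
-------
>>> from divehmm import DiveHMM
>>> from divehmm.synthetic import narwhal_like_preset, simulate
>>> dives, covs, states = simulate(narwhal_like_preset(n_dives=500), seed=1)
>>> res = DiveHMM(dives, n_states=3, family="lognormal_dep",
...               covariate_model="model2").fit(n_starts=3, seed=1)
>>> print(res.summary())  # doctest: +SKIP
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import emissions as em
from . import fitting, hmm_core
from .hmm_core import HMMParams, HMMSpec
from .preprocessing import compute_covariates
from .transitions import CovariateModel


class DiveHMM:
    """Hidden Markov model for per-dive (MD, DT, PD) responses.

    Parameters
    ----------
    dives : DataFrame
        Dive-summary table with MaxDepth, Duration, PostDiveDur and either
        Date + StartTime columns or a start_ts column.
    n_states : int
        Number of hidden behavioural states.
    family : str
        Emission family: gamma_indep, gamma_dep, lognormal_indep or
        lognormal_dep.
    covariate_model : str or CovariateModel
        Named preset ("model1".."model4", "intercept") or an explicit term
        structure.
    dependence : {"md_dt", "full"}
        Dependence structure of the dependent families.
    covariates : DataFrame, optional
        Pre-computed (tau_h, d_count, hour); computed from the dive table
        with ``deep_threshold`` if omitted.
    """

    def __init__(self, dives: pd.DataFrame, n_states: int = 3,
                 family: str = "lognormal_dep",
                 covariate_model="model1", dependence: str = "md_dt",
                 covariates: pd.DataFrame | None = None,
                 deep_threshold: float = 350.0, tau_reference: str = "end",
                 spline_df: int = 3, delta=None):
        self.dives = dives.reset_index(drop=True)
        self.endog = hmm_core.responses(self.dives)
        if covariates is None:
            covariates = compute_covariates(self.dives, deep_threshold=deep_threshold,
                                            tau_reference=tau_reference)
        self.covariates = covariates.reset_index(drop=True)
        if isinstance(covariate_model, str):
            covariate_model = CovariateModel.preset(covariate_model, m=n_states,
                                                    df=spline_df)
        self.spec = HMMSpec(m=n_states, family=family,
                            covariate_model=covariate_model,
                            dependence=dependence, delta=delta)
        self.deep_threshold = deep_threshold

    @classmethod
    def from_csv(cls, path, **kwargs) -> "DiveHMM":
        from .io import read_dive_csv
        return cls(read_dive_csv(path), **kwargs)

    @property
    def nobs(self) -> int:
        return len(self.endog)

    @property
    def n_params(self) -> int:
        return fitting.count_parameters(self.spec)

    def loglike(self, params: HMMParams) -> float:
        return hmm_core.log_likelihood(self.dives, self.covariates, self.spec, params)

    def fit(self, n_starts: int = 50, seed: int = 0, **kwargs) -> "DiveHMMResults":
        result = fitting.fit(self.dives, self.covariates, self.spec,
                             n_starts=n_starts, seed=seed, **kwargs)
        return DiveHMMResults(self, result)


class DiveHMMResults:
    """Fitted dive HMM: estimates, uncertainty and diagnostics."""

    def __init__(self, model: DiveHMM, result: fitting.FitResult):
        self.model = model
        self._result = result

    # -- estimates ---------------------------------------------------------
    @property
    def params(self) -> HMMParams:
        """Natural-scale parameters (emission block + transition coefficients)."""
        return self._result.params

    @property
    def params_working(self) -> np.ndarray:
        return self._result.working

    @property
    def param_names(self) -> list:
        return self._result.labels

    @property
    def llf(self) -> float:
        return self._result.llf

    @property
    def aic(self) -> float:
        return self._result.aic

    @property
    def nobs(self) -> int:
        return self.model.nobs

    @property
    def n_params(self) -> int:
        return self._result.n_params

    @property
    def bse(self) -> np.ndarray | None:
        """Working-scale standard errors (observed Fisher information)."""
        return self._result.se_working

    @property
    def ci_available(self) -> bool:
        return self._result.ci_available

    def conf_int(self) -> pd.DataFrame | None:
        """Natural-scale 95% Wald intervals."""
        return self._result.conf_int

    @property
    def converged(self) -> bool:
        return bool(self._result.starts["converged"].any())

    @property
    def optimizer_summary(self) -> pd.DataFrame:
        return self._result.starts

    @property
    def relabel_perm(self):
        return self._result.relabel_perm

    @property
    def degenerate_states(self) -> list:
        return self._result.degenerate_states

    # -- diagnostics -------------------------------------------------------
    def decode(self) -> np.ndarray:
        """Viterbi path (1-based; state 1 = shallowest)."""
        if len(self._result.decoded):
            return self._result.decoded
        return hmm_core.viterbi(self.model.dives, self.model.covariates,
                                self.model.spec, self.params)

    def pseudo_residuals(self) -> pd.DataFrame:
        """Forecast pseudo-residuals per dive and coordinate."""
        return hmm_core.pseudo_residuals(self.model.dives, self.model.covariates,
                                         self.model.spec, self.params)

    def moments_table(self) -> pd.DataFrame:
        """Fitted response-scale means/SDs per state (Table-4-style block)."""
        return self._result.moments_table()

    def simulate(self, n_dives: int | None = None, seed: int | None = None,
                 start="2013-08-13 12:00:00"):
        """Simulate a record from the fitted parameters (parametric
        bootstrap / model checking)."""
        from .synthetic import SimulationConfig, simulate
        config = SimulationConfig(spec=self.model.spec, params=self.params,
                                  n_dives=n_dives or self.nobs, start=start,
                                  deep_threshold=self.model.deep_threshold)
        return simulate(config, seed=seed)

    def dive_table(self) -> pd.DataFrame:
        """The input dive table with decoded state and residual columns."""
        out = self.model.dives.copy()
        out["state"] = self.decode()
        out[["z_MD", "z_DT", "z_PD"]] = self.pseudo_residuals().to_numpy()
        return out

    # -- presentation ------------------------------------------------------
    def summary(self) -> str:
        r = self._result
        spec = self.model.spec
        lines = [
            "Dive HMM fit",
            "=" * 64,
            f"states:            {spec.m}",
            f"family:            {spec.family} (dependence: {spec.dependence})",
            f"covariate model:   {spec.covariate_model.name or 'custom'}",
            f"observations:      {self.nobs}",
            f"parameters:        {self.n_params}",
            f"log-likelihood:    {self.llf:.3f}",
            f"AIC:               {self.aic:.3f}",
            f"starts (best):     {len(r.starts)} ({r.best_start})",
            "",
            "State-wise response moments (response scale)",
            "-" * 64,
            self.moments_table().round(3).to_string(),
        ]
        ci = self.conf_int()
        if ci is not None:
            lines += ["", "Estimates and 95% CI (natural scale)", "-" * 64,
                      ci.round(4).to_string()]
        else:
            lines += ["", "Confidence intervals unavailable "
                          "(Hessian not positive definite)"]
        if r.degenerate_states:
            lines += ["", f"WARNING: states {r.degenerate_states} decode to "
                          "< 1% of dives (possible overfitting)"]
        return "\n".join(lines)

    def __repr__(self):
        return (f"<DiveHMMResults: m={self.model.spec.m}, "
                f"family={self.model.spec.family}, llf={self.llf:.2f}, "
                f"AIC={self.aic:.2f}>")
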