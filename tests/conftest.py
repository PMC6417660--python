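import numpy as np
import pandas as pd
import pytest

from divehmm import emissions as em
from divehmm.hmm_core import HMMParams, HMMSpec
from divehmm.synthetic import SimulationConfig, narwhal_like_preset, simulate
from divehmm.transitions import CovariateModel


@pytest.fixture(scope="session")
def narwhal_cfg():
    return narwhal_like_preset(n_dives=2000)


@pytest.fixture(scope="session")
def narwhal_sim(narwhal_cfg):
    """One shared 2000-dive record from the narwhal-like preset."""
    return simulate(narwhal_cfg, seed=11)


def two_state_config(n_dives=400, family="lognormal_dep"):
    """Small, well-separated 2-state truth with intercept-only transitions."""
    rho = np.array([0.6, 0.5]) if family.endswith("_dep") else None
    pars = em.EmissionParams(
        family=family,
        mu=np.array([[3.6, 1.5, 1.0], [6.1, 2.45, 1.9]]),
        sigma=np.array([[0.7, 0.45, 1.0], [0.25, 0.18, 0.6]]),
        rho=rho)
    model = CovariateModel.preset("intercept", m=2)
    spec = HMMSpec(m=2, family=family, covariate_model=model)
    params = HMMParams(emission=pars, beta=np.array([-2.0, -1.5]))
    return SimulationConfig(spec=spec, params=params, n_dives=n_dives)


@pytest.fixture(scope="session")
def two_state_sim():
    cfg = two_state_config(n_dives=1000)
    dives, covs, states = simulate(cfg, seed=5)
    return cfg, dives, covs, states


def random_covariates(n, seed=0):
    rng = np.random.default_rng(seed)
    return pd.DataFrame({
        "tau_h": rng.uniform(0.0, 8.0, n),
        "d_count": rng.integers(0, 6, n).astype(float),
        "hour": rng.uniform(0.0, 24.0, n),
    })


def random_emissions(family, m=2, seed=0):
    rng = np.random.default_rng(seed)
    if family.startswith("lognormal"):
        mu = rng.normal(3.0, 1.0, (m, 3))
        sigma = rng.uniform(0.2, 1.0, (m, 3))
    else:
        mu = rng.uniform(1.0, 8.0, (m, 3))
        sigma = rng.uniform(0.5, 20.0, (m, 3))
    rho = rng.uniform(-0.7, 0.7, m) if family.endswith("_dep") else None
    return em.EmissionParams(family=family, mu=mu, sigma=sigma, rho=rho)
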