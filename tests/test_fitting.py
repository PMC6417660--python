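import numpy as np
import pandas as pd
import pytest

from divehmm import emissions as em
from divehmm import fitting
from divehmm.fitting import (_Objective, aic_table, count_parameters,
                             initial_values)
from divehmm.hmm_core import HMMParams, HMMSpec
from divehmm.synthetic import simulate
from divehmm.transitions import CovariateModel, TransitionDesign

from conftest import random_covariates, two_state_config


def _spec(m=3, family="lognormal_dep", model="model1"):
    return HMMSpec(m=m, family=family,
                   covariate_model=CovariateModel.preset(model, m=m))


# ---------------------------------------------------------------------------
# parameter counting

@pytest.mark.parametrize("m,family,model,expected", [
    (2, "lognormal_dep", "model1", 28),
    (3, "lognormal_dep", "model1", 63),
    (4, "lognormal_dep", "model1", 112),
    (2, "lognormal_indep", "model1", 26),
    (3, "lognormal_indep", "model1", 60),
    (4, "lognormal_indep", "model1", 108),
    (3, "gamma_dep", "model2", 45),
    (3, "gamma_dep", "model3", 51),
    (3, "gamma_dep", "model4", 45),
    (3, "gamma_indep", "model2", 42),
    (3, "gamma_indep", "model3", 48),
    (3, "gamma_indep", "model4", 42),
])
def test_count_parameters_reproduces_published_counts(m, family, model, expected):
    assert count_parameters(_spec(m, family, model)) == expected


# ---------------------------------------------------------------------------
# analytic score

@pytest.mark.parametrize("family", ["lognormal_indep", "lognormal_dep"])
def test_analytic_score_matches_finite_differences(family):
    cfg = two_state_config(n_dives=150, family=family)
    dives, covs, _ = simulate(cfg, seed=2)
    spec = HMMSpec(m=2, family=family,
                   covariate_model=CovariateModel.preset("model1", m=2))
    spec.covariate_model.freeze(covs)
    design = TransitionDesign(spec.covariate_model, covs)
    from divehmm.hmm_core import responses
    obj = _Objective(responses(dives), design, spec)
    rng = np.random.default_rng(3)
    theta = np.concatenate([em.to_working(cfg.params.emission),
                            rng.normal(0, 0.3, spec.covariate_model.n_params)])
    f, g = obj.value_and_grad(theta)
    assert f == pytest.approx(obj.value(theta), abs=1e-9)
    eps = 1e-6
    for i in range(0, len(theta), 3):
        e = np.zeros_like(theta)
        e[i] = eps
        fd = (obj.value(theta + e) - obj.value(theta - e)) / (2 * eps)
        assert g[i] == pytest.approx(fd, rel=5e-4, abs=5e-5)


# ---------------------------------------------------------------------------
# starting values

def test_initial_values_deterministic_and_rho_start(two_state_sim):
    _, dives, covs, _ = two_state_sim
    spec = HMMSpec(m=2, family="lognormal_dep",
                   covariate_model=CovariateModel.preset("intercept", m=2))
    s1 = initial_values(dives, spec, n_starts=1, seed=0)
    s2 = initial_values(dives, spec, n_starts=1, seed=0)
    assert len(s1) == 1
    np.testing.assert_array_equal(s1[0], s2[0])
    # dependence parameter starts at the empirical log-scale correlation
    p = fitting.unpack_params(s1[0], spec)
    x = dives[["MaxDepth", "Duration"]].to_numpy()
    want = np.corrcoef(np.log(x[:, 0]), np.log(x[:, 1]))[0, 1]
    np.testing.assert_allclose(p.emission.rho[:, 0], want, atol=1e-12)
    # transition coefficients of start 0 are zero
    assert np.all(p.beta == 0.0)


def test_initial_values_mixture_means_close_to_truth(two_state_sim):
    cfg, dives, covs, _ = two_state_sim
    spec = HMMSpec(m=2, family="lognormal_dep",
                   covariate_model=CovariateModel.preset("intercept", m=2))
    p = fitting.unpack_params(initial_values(dives, spec, 1, seed=0)[0], spec)
    # log-mean of MD within 10% of the generating values, sorted order
    np.testing.assert_allclose(p.emission.mu[:, 0], cfg.params.emission.mu[:, 0],
                               rtol=0.10)


def test_later_starts_draw_intercepts_from_grid():
    cfg = two_state_config(n_dives=200)
    dives, covs, _ = simulate(cfg, seed=4)
    spec = HMMSpec(m=2, family="lognormal_dep",
                   covariate_model=CovariateModel.preset("intercept", m=2))
    starts = initial_values(dives, spec, n_starts=6, seed=1)
    for v in starts[1:]:
        icpts = v[-2:]
        assert np.all(np.abs(icpts - np.round(icpts)) < 0.5)
        assert np.all(np.abs(icpts) <= 5.5)


# ---------------------------------------------------------------------------
# fitting

def test_single_state_lognormal_closed_form_mle():
    rng = np.random.default_rng(5)
    x = np.exp(rng.normal([3.5, 1.6, 1.1], [0.7, 0.4, 0.9], size=(600, 3)))
    dives = pd.DataFrame(x, columns=["MaxDepth", "Duration", "PostDiveDur"])
    covs = random_covariates(600, seed=5)
    spec = HMMSpec(m=1, family="lognormal_indep",
                   covariate_model=CovariateModel.preset("intercept", m=1))
    res = fitting.fit(dives, covs, spec, n_starts=1, seed=0, decode=False)
    np.testing.assert_allclose(res.params.emission.mu[0], np.log(x).mean(axis=0),
                               atol=1e-6)
    np.testing.assert_allclose(res.params.emission.sigma[0],
                               np.log(x).std(axis=0), atol=1e-6)
    # closed-form SE of the log-mean: sigma / sqrt(T)
    want_se = np.log(x).std(axis=0) / np.sqrt(len(x))
    np.testing.assert_allclose(res.se_working[:3], want_se, rtol=0.01)


def test_two_state_recovery_within_three_se(two_state_sim):
    cfg, dives, covs, states = two_state_sim
    spec = HMMSpec(m=2, family="lognormal_dep",
                   covariate_model=CovariateModel.preset("intercept", m=2))
    res = fitting.fit(dives, covs, spec, n_starts=3, seed=0)
    theta_true = fitting.pack_params(cfg.params, spec)
    dev = np.abs(res.working - theta_true) / res.se_working
    # with 16 parameters, allow one mild (< 5 SE) exceedance of the 3-SE band
    assert np.sum(dev > 3.0) <= 1 and dev.max() < 5.0
    # the optimum dominates the truth on this sample
    from divehmm import hmm_core
    assert res.llf >= hmm_core.log_likelihood(dives, covs, spec, cfg.params)
    # decoding is accurate for this separation
    assert np.mean(res.decoded == states) > 0.9


def test_fit_warns_on_small_sample():
    cfg = two_state_config(n_dives=100)
    dives, covs, _ = simulate(cfg, seed=6)
    spec = HMMSpec(m=2, family="lognormal_dep",
                   covariate_model=CovariateModel.preset("model1", m=2))
    with pytest.warns(UserWarning, match="small"):
        fitting.fit(dives, covs, spec, n_starts=1, seed=0, compute_ci=False,
                    decode=False)


def test_relabelling_permuted_start_gives_same_result(two_state_sim):
    """A fit started from a state-swapped vector lands on the same
    relabelled solution."""
    cfg, dives, covs, _ = two_state_sim
    spec = HMMSpec(m=2, family="lognormal_dep",
                   covariate_model=CovariateModel.preset("intercept", m=2))
    res = fitting.fit(dives, covs, spec, n_starts=1, seed=0, compute_ci=False)
    # swap the two state blocks of the solution and re-optimise from there
    theta = res.working.copy()
    k = em.n_working(spec.family, 2)
    per = k // 2
    swapped = np.concatenate([theta[per:k], theta[:per], theta[k:][::-1]])
    obj = _Objective(fitting.responses(dives),
                     TransitionDesign(spec.covariate_model, covs), spec)
    from scipy import optimize
    r2 = optimize.minimize(obj.value_and_grad, swapped, jac=True,
                           method="L-BFGS-B")
    theta2, perm = fitting._relabel(r2.x, spec, TransitionDesign(
        spec.covariate_model, covs))
    np.testing.assert_allclose(theta2, res.working, atol=1e-4)
    assert perm is not None and set(perm) == {0, 1}


# ---------------------------------------------------------------------------
# AIC

def _stub_fit(llf, npar, data_hash="h", family="lognormal_dep", name="model1"):
    spec = _spec(3, family, name)
    return fitting.FitResult(
        spec=spec, params=None, working=None, llf=llf, n_params=npar,
        aic=-2 * llf + 2 * npar, se_working=None, conf_int=None, labels=[],
        starts=pd.DataFrame(), best_start=0, relabel_perm=None,
        decoded=np.empty(0, dtype=int), degenerate_states=[],
        data_hash=data_hash)


def test_aic_table_ranking():
    single = aic_table([_stub_fit(-100.0, 60)])
    assert single.loc[0, "dAIC"] == 0.0
    tab = aic_table([_stub_fit(-100.0, 63), _stub_fit(-100.0, 60)])
    np.testing.assert_allclose(tab["dAIC"], [0.0, 6.0])
    assert tab.loc[0, "np"] == 60
    with pytest.raises(ValueError):
        aic_table([_stub_fit(-1.0, 60, "a"), _stub_fit(-1.0, 60, "b")])


# ---------------------------------------------------------------------------
# confidence intervals

def test_ci_coverage_single_state():
    """Wald 95% CI for the MD log-mean: coverage within (88%, 99%) over
    200 simulated refits."""
    mu_true, sig_true = 4.0, 0.8
    rng = np.random.default_rng(7)
    spec = HMMSpec(m=1, family="lognormal_indep",
                   covariate_model=CovariateModel.preset("intercept", m=1))
    covs = random_covariates(400, seed=7)
    hits = 0
    n_rep = 200
    for _ in range(n_rep):
        x = np.exp(rng.normal([mu_true, 1.5, 1.0], [sig_true, 0.4, 0.8],
                              size=(400, 3)))
        dives = pd.DataFrame(x, columns=["MaxDepth", "Duration", "PostDiveDur"])
        res = fitting.fit(dives, covs, spec, n_starts=1, seed=0, decode=False)
        lo, hi = res.conf_int.loc["mu[1,MD]", ["lower", "upper"]]
        hits += lo <= mu_true <= hi
    assert 0.88 <= hits / n_rep <= 0.99


def test_ci_width_shrinks_with_sample_size(two_state_sim):
    cfg, dives, covs, _ = two_state_sim
    spec = HMMSpec(m=2, family="lognormal_dep",
                   covariate_model=CovariateModel.preset("intercept", m=2))
    res_big = fitting.fit(dives, covs, spec, n_starts=1, seed=0, decode=False)
    spec2 = HMMSpec(m=2, family="lognormal_dep",
                    covariate_model=CovariateModel.preset("intercept", m=2))
    res_small = fitting.fit(dives.iloc[:200], covs.iloc[:200], spec2,
                            n_starts=1, seed=0, decode=False)
    assert np.all(res_small.se_working[:14] > res_big.se_working[:14])
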