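import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from divehmm import emissions as em
from divehmm.transitions import (CovariateModel, NaturalSplineBasis,
                                 PeriodicSplineBasis, TransitionDesign,
                                 transition_matrix)

from conftest import random_covariates


# ---------------------------------------------------------------------------
# independent Cox-de Boor recursion oracle

def deboor(x, knots, degree, j):
    if degree == 0:
        return 1.0 if knots[j] <= x < knots[j + 1] else 0.0
    val = 0.0
    den = knots[j + degree] - knots[j]
    if den > 0:
        val += (x - knots[j]) / den * deboor(x, knots, degree - 1, j)
    den = knots[j + degree + 1] - knots[j + 1]
    if den > 0:
        val += (knots[j + degree + 1] - x) / den * deboor(x, knots, degree - 1, j + 1)
    return val


def test_cubic_bspline_columns_match_de_boor_oracle():
    from divehmm.transitions import _bspline_columns
    knots = np.array([0.0, 0, 0, 0, 1.5, 3.0, 5, 5, 5, 5])
    x = np.array([0.3, 1.1, 2.0, 3.7, 4.9])
    got = _bspline_columns(x, knots)
    want = np.array([[deboor(xi, knots, 3, j) for j in range(len(knots) - 4)]
                     for xi in x])
    np.testing.assert_allclose(got, want, atol=1e-12)


def test_periodic_basis_matches_wrapped_de_boor_oracle():
    basis = PeriodicSplineBasis(df=3, period=24.0)
    h = np.array([6.0, 12.0, 18.0])
    got = basis.design(h)
    step = 24.0 / 4
    knots = np.arange(5) * step
    want = np.zeros((3, 4))
    for j in range(4):
        for s in range(-2, 3):
            for r, hi in enumerate(h):
                want[r, j] += deboor(hi - j * step + s * 24.0, knots, 3, 0)
    np.testing.assert_allclose(got, want[:, 1:], atol=1e-12)


# ---------------------------------------------------------------------------
# natural splines

def test_natural_spline_linear_beyond_boundary_knots():
    basis = NaturalSplineBasis(np.array([2.0, 4.0]), (0.0, 6.0))
    x = np.array([-3.0, -2.0, -1.0, 7.0, 8.0, 9.0])
    b = basis.design(x)
    # second differences vanish on each linear tail
    np.testing.assert_allclose(b[2] - 2 * b[1] + b[0], 0.0, atol=1e-10)
    np.testing.assert_allclose(b[5] - 2 * b[4] + b[3], 0.0, atol=1e-10)
    # and the second derivative is ~0 at the boundary knots themselves
    eps = 1e-5
    for bk in (0.0, 6.0):
        pts = basis.design(np.array([bk - eps, bk, bk + eps]))
        d2 = (pts[2] - 2 * pts[1] + pts[0]) / eps ** 2
        np.testing.assert_allclose(d2, 0.0, atol=1e-4)


def test_natural_spline_spans_de_boor_bsplines():
    """Every natural-basis column is a combination of the raw cubic
    B-splines on the same knots (checked against the de Boor oracle)."""
    basis = NaturalSplineBasis(np.array([1.0, 3.0]), (0.0, 5.0))
    x = np.linspace(0.0, 5.0, 41)
    nat = basis.design(x)
    knots = np.concatenate([[0.0] * 4, [1.0, 3.0], [5.0] * 4])
    raw = np.array([[deboor(xi, knots, 3, j) for j in range(6)] for xi in x])
    raw[-1, -1] = 1.0  # half-open convention at the right endpoint
    coef, res, *_ = np.linalg.lstsq(raw, nat, rcond=None)
    np.testing.assert_allclose(raw @ coef, nat, atol=1e-8)


def test_natural_spline_quantile_knots_and_degenerate_input():
    x = np.concatenate([np.linspace(0, 9, 900), [10.0]])
    basis = NaturalSplineBasis.from_data(x, df=3)
    assert basis.df == 3
    assert basis.boundary_knots == (0.0, 10.0)
    np.testing.assert_allclose(basis.interior_knots, np.quantile(x, [1 / 3, 2 / 3]))
    with pytest.warns(UserWarning):
        degen = NaturalSplineBasis.from_data(np.full(10, 2.0), df=3)
    b = degen.design(np.array([1.0, 2.0, 3.0]))
    assert np.ptp(b, axis=0).max() == 0.0  # constant columns


# ---------------------------------------------------------------------------
# periodic splines

def test_periodic_basis_is_periodic_and_smooth():
    basis = PeriodicSplineBasis(df=3)
    left = basis.design(np.array([0.0]))
    right = basis.design(np.array([24.0 - 1e-9]))
    np.testing.assert_allclose(left, right, atol=1e-6)
    # wrapped evaluation: h and (h + 24) mod 24 agree
    h = np.array([5.3, 11.7, 22.9])
    np.testing.assert_allclose(basis.design(h), basis.design((h + 24.0) % 24.0),
                               atol=1e-12)
    # first and second derivatives match across the boundary
    eps = 1e-4
    for nu in (1, 2):
        a = np.diff(basis.design(np.array([0.0, eps, 2 * eps])), n=nu, axis=0)[0]
        b = np.diff(basis.design(np.array([24.0 - 3 * eps, 24.0 - 2 * eps,
                                           24.0 - eps])), n=nu, axis=0)[-1]
        np.testing.assert_allclose(a, b, atol=1e-4 if nu == 1 else 2e-2)


def test_periodic_basis_rejects_out_of_range():
    with pytest.raises(ValueError):
        PeriodicSplineBasis().design(np.array([24.0]))
    with pytest.raises(ValueError):
        PeriodicSplineBasis().design(np.array([-0.1]))


# ---------------------------------------------------------------------------
# softmax link

def test_transition_matrix_uniform_and_closed_form():
    np.testing.assert_allclose(transition_matrix(np.zeros((3, 3))),
                               np.full((3, 3), 1 / 3))
    row = transition_matrix(np.array([[0.0, np.log(2.0), np.log(4.0)]]))
    np.testing.assert_allclose(row[0], [1 / 7, 2 / 7, 4 / 7], atol=1e-14)


@settings(derandomize=True, max_examples=50, deadline=None)
@given(st.integers(0, 2 ** 31 - 1))
def test_transition_matrix_rows_stochastic_and_shift_invariant(seed):
    rng = np.random.default_rng(seed)
    eta = rng.normal(0, 5, (20, 3, 3))
    om = transition_matrix(eta)
    assert np.all(om > 0)
    np.testing.assert_allclose(om.sum(axis=-1), 1.0, atol=1e-12)
    shifted = transition_matrix(eta + rng.normal(0, 3, (20, 3, 1)))
    np.testing.assert_allclose(om, shifted, atol=1e-10)


def test_transition_matrix_overflow_safe():
    om = transition_matrix(np.array([[0.0, 800.0, -800.0]]))
    assert np.all(np.isfinite(om)) and abs(om.sum() - 1.0) < 1e-12


# ---------------------------------------------------------------------------
# covariate model / design

def test_preset_parameter_counts():
    # per predictor: 1 intercept + 3 per spline term
    assert CovariateModel.preset("model1", m=3).n_params == 42
    assert CovariateModel.preset("model1", m=2).n_params == 14
    assert CovariateModel.preset("model1", m=4).n_params == 84
    assert CovariateModel.preset("model2", m=3).n_params == 24
    assert CovariateModel.preset("model3", m=3).n_params == 30
    assert CovariateModel.preset("model4", m=3).n_params == 24


def test_model2_ignores_tau_and_d():
    covs = random_covariates(50, seed=1)
    model = CovariateModel.preset("model2", m=3).freeze(covs)
    design = TransitionDesign(model, covs)
    beta = np.random.default_rng(2).normal(0, 1, model.n_params)
    eta1 = design.eta(beta)
    perturbed = covs.copy()
    perturbed["tau_h"] += 5.0
    perturbed["d_count"] += 3.0
    eta2 = TransitionDesign(model, perturbed).eta(beta)
    np.testing.assert_array_equal(eta1, eta2)


def test_model1_predictor_dot_product_oracle():
    covs = random_covariates(10, seed=3)
    model = CovariateModel.preset("model1", m=3).freeze(covs)
    design = TransitionDesign(model, covs)
    rng = np.random.default_rng(4)
    beta = rng.normal(0, 1, model.n_params)
    eta = design.eta(beta)
    assert np.all(np.diagonal(eta, axis1=1, axis2=2) == 0.0)
    # hand-compute eta_12 = intercept + T-basis . theta + H-basis . delta
    t = 4
    sl = design.slices[(1, 2)]
    b = beta[sl]
    bt = model.tau_basis.design([covs["tau_h"][t]])[0]
    bh = model.hour_basis.design([covs["hour"][t]])[0]
    want = b[0] + bt @ b[1:4] + bh @ b[4:7]
    assert abs(eta[t, 0, 1] - want) < 1e-12
    # eta_31 uses the d spline
    sl = design.slices[(3, 1)]
    b = beta[sl]
    bd = model.d_basis.design([covs["d_count"][t]])[0]
    want = b[0] + bd @ b[1:4] + bh @ b[4:7]
    assert abs(eta[t, 2, 0] - want) < 1e-12


def test_zero_coefficients_give_zero_eta_and_uniform_rows():
    covs = random_covariates(10, seed=5)
    model = CovariateModel.preset("model1", m=3).freeze(covs)
    design = TransitionDesign(model, covs)
    assert np.all(design.eta(np.zeros(model.n_params)) == 0.0)
    np.testing.assert_allclose(design.matrices(np.zeros(model.n_params)),
                               1 / 3, atol=1e-14)


def test_config_grammar_and_validation():
    model = CovariateModel.from_config(
        3, {"1->2": ["intercept", "T", "H"], "3->1": ["intercept", "D", "H"]})
    assert model.terms[(1, 2)] == ("T", "H")
    assert model.terms[(3, 1)] == ("D", "H")
    assert model.terms[(2, 3)] == ()
    with pytest.raises(ValueError):
        CovariateModel(m=2, terms={(1, 1): ("T",)})
    with pytest.raises(ValueError):
        CovariateModel(m=2, terms={(1, 2): ("Q",)})


def test_permutation_invariance_of_term_structures():
    m1 = CovariateModel.preset("model1", m=3)
    m2 = CovariateModel.preset("model2", m=3)
    swap12 = np.array([1, 0, 2])
    swap23 = np.array([0, 2, 1])
    assert m2.permutation_invariant(swap12) and m2.permutation_invariant(swap23)
    assert m1.permutation_invariant(swap12)       # states 1,2 share term sets
    assert not m1.permutation_invariant(swap23)   # deep state is special
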