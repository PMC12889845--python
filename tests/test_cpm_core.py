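"""Unit and property tests for the CPM NPMLE machinery."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import optimize
from scipy.special import ndtr, ndtri

from mwcpm import (
    FitOptions,
    alpha_step,
    build_design,
    conditional_cdf,
    cpm_negative_loglik,
    fit_cpm,
    index_outcomes,
    make_link,
)


# ---------------------------------------------------------------------------
# outcome indexing
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "y, uniq, counts, ranks",
    [
        ([1.2, 1.2, 3.0], [1.2, 3.0], [2, 1], [0, 0, 1]),
        ([5, 1, 3], [1, 3, 5], [1, 1, 1], [2, 0, 1]),
        ([7, 7], [7], [2], [0, 0]),
    ],
)
def test_index_outcomes_examples(y, uniq, counts, ranks):
    idx = index_outcomes(y)
    assert np.array_equal(idx.unique_values, uniq)
    assert np.array_equal(idx.counts, counts)
    assert np.array_equal(idx.obs_rank, ranks)


@given(st.lists(st.integers(min_value=-50, max_value=50), min_size=1, max_size=60))
@settings(deadline=None, derandomize=True)
def test_index_outcomes_properties(values):
    idx = index_outcomes(values)
    assert np.all(np.diff(idx.unique_values) > 0)
    assert idx.counts.sum() == len(values)
    # round trip: the indexed value is the original value
    assert np.array_equal(idx.unique_values[idx.obs_rank], values)


def test_index_outcomes_rejects_bad_input():
    with pytest.raises(ValueError):
        index_outcomes([])
    with pytest.raises(ValueError):
        index_outcomes([1.0, np.nan])
    with pytest.raises(ValueError):
        index_outcomes(np.array([1.0, "micro", 3], dtype=object))


# ---------------------------------------------------------------------------
# links
# ---------------------------------------------------------------------------

# round-trip ranges per link limited by double precision: beyond the upper
# bound 1 - F(x) is smaller than the spacing of floats near 1 and the inverse
# cannot resolve x
@pytest.mark.parametrize(
    "name, lo, hi", [("probit", -8, 4), ("logit", -8, 8), ("loglog", -5.5, 8)]
)
def test_link_roundtrip_and_shape(name, lo, hi):
    link = make_link(name)
    x = np.linspace(lo, hi, 101)
    p = link.g_inv(x)
    assert np.all(np.diff(p) > 0)
    assert np.max(np.abs(link.g(p) - x)) < 1e-10
    assert link.g_inv(-np.inf) == 0.0 and link.g_inv(np.inf) == 1.0
    assert link.g_inv_deriv(-np.inf) == 0.0 and link.g_inv_deriv(np.inf) == 0.0


def test_link_center_values():
    assert make_link("probit").g_inv(0.0) == pytest.approx(0.5)
    assert make_link("logit").g_inv(0.0) == pytest.approx(0.5)
    assert make_link("logit").g(0.5) == pytest.approx(0.0)
    # G(p) = -log(-log p) evaluated at x=0 gives p = e^{-1}
    assert make_link("loglog").g_inv(0.0) == pytest.approx(np.exp(-1), abs=1e-12)


def test_unknown_link_errors():
    with pytest.raises(ValueError, match="probit"):
        make_link("cauchit")


# ---------------------------------------------------------------------------
# negative log-likelihood
# ---------------------------------------------------------------------------

def test_nll_single_observation_is_zero():
    design = build_design([7.0])
    nll, grad = cpm_negative_loglik(np.zeros(0), np.zeros(0), 0.0, design, make_link("probit"))
    assert nll == 0.0
    assert grad.size == 0


def test_nll_intercept_only_minimized_at_link_ecdf():
    # J=2 with counts (3, 5): the NPMLE intercept is G(3/8)
    design = build_design([0, 0, 0, 1, 1, 1, 1, 1])
    link = make_link("probit")
    a_star = ndtri(3 / 8)
    nll_star, grad = cpm_negative_loglik([a_star], np.zeros(0), 0.0, design, link)
    assert abs(grad[0]) < 1e-10
    expected = -(3 * np.log(3 / 8) + 5 * np.log(5 / 8))
    assert nll_star == pytest.approx(expected, rel=1e-12)
    for delta in (-0.3, 0.2):
        nll_off, _ = cpm_negative_loglik([a_star + delta], np.zeros(0), 0.0, design, link)
        assert nll_off > nll_star


def test_nll_flags_nonincreasing_alpha():
    design = build_design([1.0, 2.0, 3.0])
    nll, _ = cpm_negative_loglik([0.5, 0.5], np.zeros(0), 0.0, design, make_link("logit"))
    assert nll == np.inf


@pytest.mark.parametrize("name", ["probit", "logit", "loglog"])
def test_analytic_gradient_matches_finite_differences(name, rng):
    n = 8
    x = rng.standard_normal(n)
    a = np.array([0, 1, 0, 1, 1, 0, 0, 1], dtype=float)
    y = rng.exponential(size=n)
    design = build_design(y, a, x)
    link = make_link(name)
    J = design.outcome_index.n_unique
    alpha0 = ndtri((np.arange(1, J) / J))
    beta0, tau0 = np.array([0.3]), -0.2

    def pack_nll(theta):
        return cpm_negative_loglik(theta[: J - 1], theta[J - 1 : J], theta[J], design, link)[0]

    theta = np.concatenate([alpha0, beta0, [tau0]])
    _, analytic = cpm_negative_loglik(alpha0, beta0, tau0, design, link)
    numeric = optimize.approx_fprime(theta, pack_nll, 1e-7)
    assert np.max(np.abs(analytic - numeric)) / max(1.0, np.max(np.abs(numeric))) < 1e-6


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def test_null_fit_recovers_ecdf(rng):
    y = rng.exponential(size=37)
    design = build_design(y)
    fit = fit_cpm(design, "probit")
    assert fit.converged
    ecdf = np.cumsum(design.outcome_index.counts[:-1]) / 37
    assert np.max(np.abs(ndtr(fit.alpha) - ecdf)) < 1e-8
    # fitted conditional CDF equals ECDF at every unique value, any covariates
    for k, y_k in enumerate(design.outcome_index.unique_values[:-1]):
        assert conditional_cdf(fit, y_k) == pytest.approx(ecdf[k], abs=1e-8)


def test_fit_invariant_to_monotone_transformation(small_sim):
    data = small_sim
    fits = [
        fit_cpm(build_design(t(data.Y), data.A, data.X), "probit")
        for t in (lambda y: y, np.log, lambda y: y ** (1 / 3))
    ]
    ref = fits[0]
    for other in fits[1:]:
        assert other.converged
        assert np.max(np.abs(other.beta - ref.beta)) < 1e-6
        assert abs(other.tau - ref.tau) < 1e-6
        assert abs(other.loglik - ref.loglik) < 1e-6


def _nll_reference(theta, y, x, a):
    """Independent likelihood evaluation for the oracle check (probit)."""
    order = np.unique(y)
    J = order.size
    alpha = np.concatenate([[-np.inf], theta[: J - 1], [np.inf]])
    eta = theta[J - 1] * x + theta[J] * a
    total = 0.0
    for yi, ei in zip(y, eta):
        k = int(np.searchsorted(order, yi)) + 1
        p = ndtr(alpha[k] - ei) - ndtr(alpha[k - 1] - ei)
        total -= np.log(p)
    return total


def test_npmle_matches_generic_optimizer_small_n(rng):
    n = 6
    x = rng.standard_normal(n)
    a = np.array([0, 1, 0, 1, 1, 0], dtype=float)
    y = rng.exponential(size=n)
    fit = fit_cpm(build_design(y, a, x), "probit")
    assert fit.converged

    J = n  # continuous draws: all values distinct

    def objective(z):
        # same monotone parameterization, likelihood written independently
        alpha = np.concatenate([[z[0]], z[0] + np.cumsum(np.exp(z[1 : J - 1]))])
        return _nll_reference(np.concatenate([alpha, z[J - 1 :]]), y, x, a)

    z0 = np.concatenate([[fit.alpha[0]], np.log(np.diff(fit.alpha)), fit.beta, [fit.tau]])
    z0 = z0 + 0.05 * rng.standard_normal(z0.size)  # perturb away from our solution
    res = optimize.minimize(
        objective, z0, method="Nelder-Mead",
        options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 40000, "maxfev": 40000},
    )
    assert abs(-fit.loglik - res.fun) < 1e-6


def test_loglik_matches_independent_ordinal_regression(rng):
    # outcomes as ordered categories: the CPM likelihood is the standard
    # cumulative-link multinomial likelihood
    from statsmodels.miscmodels.ordinal_model import OrderedModel

    n = 60
    x = rng.standard_normal(n)
    a = (rng.random(n) < 0.5).astype(float)
    y = np.clip(np.round(np.exp(0.4 * x + 0.5 * a + rng.standard_normal(n))), 0, 5)
    for distr in ("probit", "logit"):
        fit = fit_cpm(build_design(y, a, x), distr)
        sm_fit = OrderedModel(
            pd.Series(y).rank(method="dense").astype(int),
            np.column_stack([x, a]),
            distr=distr,
        ).fit(method="bfgs", maxiter=500, disp=0)
        assert fit.converged
        assert fit.loglik == pytest.approx(sm_fit.llf, abs=1e-4)
        assert fit.beta[0] == pytest.approx(sm_fit.params.iloc[0], abs=1e-4)
        assert fit.tau == pytest.approx(sm_fit.params.iloc[1], abs=1e-4)


def test_degenerate_single_value_outcome():
    fit = fit_cpm(build_design([7.0, 7.0]), "logit")
    assert fit.converged
    assert fit.alpha.size == 0
    assert fit.loglik == 0.0


def test_nonconvergence_is_reported_not_raised():
    # complete separation: treated arm occupies the upper outcome block
    y = np.arange(20, dtype=float)
    a = (y >= 10).astype(float)
    fit = fit_cpm(build_design(y, a), "probit", FitOptions(maxiter=150))
    assert not fit.converged  # tau diverges; flagged, no exception


# ---------------------------------------------------------------------------
# step function and conditional CDF
# ---------------------------------------------------------------------------

def test_alpha_step_conventions(rng):
    y = np.array([1.0, 2.0, 2.0, 5.0])
    fit = fit_cpm(build_design(y), "probit")
    vals = fit.outcome_index.unique_values
    assert alpha_step(fit, 0.5) == -np.inf
    assert alpha_step(fit, vals[0]) == fit.alpha[0]
    assert alpha_step(fit, 3.7) == fit.alpha[1]  # between 2 and 5
    assert alpha_step(fit, vals[-1]) == np.inf
    assert alpha_step(fit, 99.0) == np.inf
    assert conditional_cdf(fit, 0.5) == 0.0
    assert conditional_cdf(fit, vals[-1]) == 1.0


def test_conditional_cdf_monotone_in_y(small_sim):
    data = small_sim
    fit = fit_cpm(build_design(data.Y, data.A, data.X), "probit")
    grid = fit.outcome_index.unique_values
    for a in (0, 1):
        vals = conditional_cdf(fit, grid, x=[0.3], a=a)
        assert np.all(np.diff(vals) >= 0)
        assert 0 <= vals[0] and vals[-1] == 1.0


def test_conditional_cdf_dimension_mismatch(small_sim):
    data = small_sim
    fit = fit_cpm(build_design(data.Y, data.A, data.X), "probit")
    with pytest.raises(ValueError, match="length 1"):
        conditional_cdf(fit, 1.0, x=[0.1, 0.2])
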