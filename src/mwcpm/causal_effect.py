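"""Mann-Whitney-type causal effect estimation from a fitted CPM.

The estimand is theta = P(Y_i(1) > Y_j(0)) + 0.5 P(Y_i(1) = Y_j(0)) for two
independent units i, j: the probability that a randomly chosen unit's
potential outcome under treatment exceeds an independent unit's potential
outcome under control, with ties split.  Under consistency, no interference,
ignorability given X, and positivity, the marginal potential-outcome CDF is
identified by standardization:

    F_{Y(a)}(y) = E_X[ P(Y <= y | X, A = a) ],

estimated by plugging the fitted CPM conditional CDF into the empirical
distribution of X (averaging over all n rows, both arms).  theta is then the
Mann-Whitney functional of the two estimated marginal CDFs, computed over the
grid of unique observed outcome values.  Inference is by the nonparametric
bootstrap.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .cpm_core import (
    CPMDesign,
    CPMFit,
    FitOptions,
    build_design,
    fit_cpm,
    make_link,
)

__all__ = [
    "MarginalPotentialCDF",
    "ThetaEstimate",
    "CPMConvergenceError",
    "marginal_cdf",
    "mw_kernel",
    "theta_from_cdfs",
    "estimate_theta",
    "bootstrap_theta",
]


class CPMConvergenceError(RuntimeError):
    """Raised when a CPM fit required for estimation did not converge."""

    def __init__(self, fit: CPMFit | None = None, message: str = ""):
        self.fit = fit
        detail = message or "CPM fit did not converge"
        if fit is not None:
            detail += (
                f" (n_iter={fit.n_iter}, gradient_norm={fit.gradient_norm:.3g},"
                f" message={fit.message!r})"
            )
        super().__init__(detail)


@dataclass(frozen=True)
class MarginalPotentialCDF:
    """Estimated marginal CDF of the potential outcome Y(a) on the unique-value grid."""

    arm: int
    grid: np.ndarray
    cdf: np.ndarray  # length J, cdf[-1] == 1 exactly
    pmf: np.ndarray  # increments, pmf >= 0, sums to 1


@dataclass(frozen=True)
class ThetaEstimate:
    """Point estimate of theta with optional bootstrap uncertainty."""

    theta_hat: float
    se: Optional[float] = None
    ci_low: Optional[float] = None
    ci_high: Optional[float] = None
    n_boot: int = 0
    n_boot_failed: int = 0
    method: Optional[str] = None


def marginal_cdf(fit: CPMFit, design: CPMDesign, a: int) -> MarginalPotentialCDF:
    """Standardized (plug-in) marginal CDF of Y(a).

    Averages the fitted conditional CDF, with treatment set counterfactually
    to ``a`` for every row, over the empirical covariate distribution of the
    full estimation sample:

        F_hat(y_(k)) = (1/n) sum_i G^{-1}(alpha_k - beta' x_i - tau a)

    for k < J, with F_hat at the largest unique value fixed to 1.
    """
    if not fit.converged:
        raise CPMConvergenceError(fit, "cannot standardize a non-converged fit")
    if a not in (0, 1):
        raise ValueError("arm must be 0 or 1")
    index = fit.outcome_index
    J = index.n_unique
    eta = design.X @ fit.beta
    if fit.has_treatment:
        eta = eta + fit.tau * a
    elif a == 1:
        raise ValueError("fit has no treatment term; only arm a=0 is defined")
    if J > 1:
        u = fit.alpha[:, None] - eta[None, :]
        body = fit.link.g_inv(u).mean(axis=1)
    else:
        body = np.zeros(0)
    cdf = np.concatenate([body, [1.0]])
    pmf = np.diff(cdf, prepend=0.0)
    return MarginalPotentialCDF(arm=int(a), grid=index.unique_values, cdf=cdf, pmf=pmf)


def mw_kernel(y1, y0):
    """Mann-Whitney tie-splitting kernel h(y1, y0) = I(y1 > y0) + 0.5 I(y1 = y0).

    Satisfies h(a, b) + h(b, a) = 1.  Works elementwise on arrays.
    """
    y1_arr = np.asarray(y1)
    y0_arr = np.asarray(y0)
    out = np.where(y1_arr > y0_arr, 1.0, np.where(y1_arr == y0_arr, 0.5, 0.0))
    if np.isscalar(y1) and np.isscalar(y0):
        return float(out)
    return out


def theta_from_cdfs(F1: MarginalPotentialCDF, F0: MarginalPotentialCDF) -> float:
    """Mann-Whitney functional of two marginal CDFs sharing a grid.

    theta = sum_{k,l} h(y_(k), y_(l)) pmf1[k] pmf0[l], evaluated by the O(J)
    accumulation sum_k pmf1[k] (cdf0[k-1] + 0.5 pmf0[k]).
    """
    if F1.grid.shape != F0.grid.shape or not np.array_equal(F1.grid, F0.grid):
        raise ValueError("marginal CDFs must share the same outcome grid")
    cdf0_prev = F0.cdf - F0.pmf
    theta = float(np.sum(F1.pmf * (cdf0_prev + 0.5 * F0.pmf)))
    return min(max(theta, 0.0), 1.0)


def _theta_exclude_diagonal(F1, F0, counts) -> float:
    """Variant excluding same-observation pairs from the double sum.

    Each unique value's pmf mass is split evenly over its tied observations,
    the observation-level diagonal is removed, and the remaining kernel mass
    renormalized so the result stays a probability.
    """
    theta_all = theta_from_cdfs(F1, F0)
    diag_w = np.sum(F1.pmf * F0.pmf / counts)
    if diag_w >= 1.0:
        raise ValueError("degenerate distribution: all mass on the diagonal")
    return float((theta_all - 0.5 * diag_w) / (1.0 - diag_w))


def estimate_theta(
    y,
    a,
    x=None,
    link="probit",
    *,
    exclude_diagonal: bool = False,
    fit_options: FitOptions | None = None,
) -> ThetaEstimate:
    """Point estimate of theta from a CPM fit (no uncertainty).

    Fits G[P(Y <= y | X, A)] = alpha(y) - beta'X - tau A by NPMLE,
    standardizes both arms' marginal CDFs over the empirical covariate
    distribution, and evaluates the Mann-Whitney functional.  Deterministic
    given the data.

    Raises
    ------
    CPMConvergenceError
        When the NPMLE iteration fails; batch callers should record a failure.
    ValueError
        When a treatment arm is absent.
    """
    if a is None:
        raise ValueError("treatment indicator is required to estimate theta")
    a_arr = np.asarray(a, dtype=float)
    if not (np.any(a_arr == 0) and np.any(a_arr == 1)):
        raise ValueError("both treatment arms must be present")
    design = build_design(y, a_arr, x)
    fit = fit_cpm(design, make_link(link), fit_options)
    if not fit.converged:
        raise CPMConvergenceError(fit)
    F1 = marginal_cdf(fit, design, a=1)
    F0 = marginal_cdf(fit, design, a=0)
    if exclude_diagonal:
        theta = _theta_exclude_diagonal(F1, F0, design.outcome_index.counts)
    else:
        theta = theta_from_cdfs(F1, F0)
    return ThetaEstimate(theta_hat=theta)


def bootstrap_theta(
    y,
    a,
    x=None,
    link="probit",
    *,
    B: int = 200,
    seed=None,
    method: str = "normal_interval",
    stratified: bool = False,
    max_failure_fraction: float = 0.1,
    fit_options: FitOptions | None = None,
) -> ThetaEstimate:
    """theta with a bootstrap standard error and 95% confidence interval.

    Draws ``B`` nonparametric resamples of rows (with replacement, size n;
    optionally stratified by treatment arm), re-estimates theta on each, and
    forms the default interval theta_hat +/- 1.96 SD(theta*) clipped to
    [0, 1].  ``method='percentile'`` uses the 2.5/97.5 empirical percentiles
    instead.  Resamples whose CPM refit fails are dropped and counted in
    ``n_boot_failed``; more than ``max_failure_fraction`` of failures raises,
    since the SD would be unreliable.
    """
    if B < 2:
        raise ValueError("B must be at least 2")
    if method not in ("normal_interval", "percentile"):
        raise ValueError("method must be 'normal_interval' or 'percentile'")
    y = np.asarray(y)
    a = np.asarray(a, dtype=float)
    x_arr = None if x is None else np.asarray(x, dtype=float)
    point = estimate_theta(y, a, x_arr, link, fit_options=fit_options)
    rng = np.random.default_rng(seed)
    n = y.shape[0]
    if stratified:
        arm_idx = [np.flatnonzero(a == v) for v in (0.0, 1.0)]
    thetas = []
    failed = 0
    for _ in range(B):
        if stratified:
            idx = np.concatenate([g[rng.integers(0, g.size, g.size)] for g in arm_idx])
        else:
            idx = rng.integers(0, n, n)
        xb = None if x_arr is None else x_arr[idx]
        try:
            rep = estimate_theta(y[idx], a[idx], xb, link, fit_options=fit_options)
        except (CPMConvergenceError, ValueError):
            # ValueError covers resamples that lost an arm entirely
            failed += 1
            continue
        thetas.append(rep.theta_hat)
    if failed > max_failure_fraction * B:
        raise CPMConvergenceError(
            None,
            f"{failed}/{B} bootstrap refits failed; interval would be unreliable",
        )
    thetas = np.asarray(thetas)
    se = float(np.std(thetas, ddof=1))
    if method == "normal_interval":
        lo, hi = point.theta_hat - 1.96 * se, point.theta_hat + 1.96 * se
    else:
        lo, hi = np.percentile(thetas, [2.5, 97.5])
    return ThetaEstimate(
        theta_hat=point.theta_hat,
        se=se,
        ci_low=float(min(max(lo, 0.0), 1.0)),
        ci_high=float(min(max(hi, 0.0), 1.0)),
        n_boot=int(thetas.size),
        n_boot_failed=failed,
        method=method,
    )
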