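"""Cumulative probability models (CPMs) fit by nonparametric maximum likelihood.

A CPM specifies the conditional distribution of an orderable outcome Y given
covariates X and a binary treatment A through

    G[ P(Y <= y | X, A) ] = alpha(y) - beta' X - tau A,

where G is a known link function and the intercept function alpha(.) is an
unspecified increasing step function estimated jointly with (beta, tau).
Equivalently, Y follows a semiparametric linear transformation model
H^{-1}(Y) = beta' X + tau A + eps with eps ~ F_eps = G^{-1} and H monotone but
otherwise unrestricted; alpha plays the role of H^{-1} evaluated at the
observed outcome values.  Because alpha is estimated nonparametrically, the
fitted slopes (and everything derived from the fitted conditional CDF) are
invariant to strictly increasing transformations of Y: the model is
rank-based.

The nonparametric likelihood is the multinomial likelihood of a cumulative
link model that treats the J unique outcome values as ordered categories; the
NPMLE maximizes it jointly over the J-1 finite intercepts and the regression
coefficients.  Monotonicity of the intercepts is enforced by optimizing over
(alpha_1, log successive differences), so every iterate corresponds to a valid
CDF.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Optional, Sequence

import numpy as np
from scipy import optimize, special

__all__ = [
    "UniqueOutcomeIndex",
    "LinkFunction",
    "CPMDesign",
    "CPMFit",
    "FitOptions",
    "index_outcomes",
    "make_link",
    "build_design",
    "cpm_negative_loglik",
    "fit_cpm",
    "alpha_step",
    "conditional_cdf",
]

#: floor applied to cell probabilities inside the log-likelihood.  A solution
#: that still relies on the floor is flagged as non-converged: it indicates
#: boundary escape (e.g. separation), not a genuine NPMLE.
PROB_FLOOR = 1e-12


# ---------------------------------------------------------------------------
# outcome indexing
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class UniqueOutcomeIndex:
    """Sorted unique outcome values with multiplicities.

    All intercepts and estimated CDFs live on this support.

    Attributes
    ----------
    unique_values : (J,) ndarray, strictly increasing
    counts : (J,) ndarray of positive ints, summing to the sample size
    obs_rank : (n,) ndarray of 0-based indices into ``unique_values``
    """

    unique_values: np.ndarray
    counts: np.ndarray
    obs_rank: np.ndarray

    @property
    def n_unique(self) -> int:
        return int(self.unique_values.shape[0])

    @property
    def n_obs(self) -> int:
        return int(self.obs_rank.shape[0])


def index_outcomes(y: Sequence) -> UniqueOutcomeIndex:
    """Index an outcome vector by its sorted unique values.

    Parameters
    ----------
    y : sequence of orderable scalars (continuous, ordinal codes, or a mix).

    Raises
    ------
    ValueError
        On empty input, NaN, or values that are not mutually orderable.
    """
    arr = np.asarray(y)
    if arr.ndim != 1 or arr.size == 0:
        raise ValueError("outcome must be a non-empty 1-d vector")
    if arr.dtype.kind == "f" and np.isnan(arr).any():
        raise ValueError("outcome contains NaN; drop or impute before indexing")
    try:
        uniq, inverse, counts = np.unique(arr, return_inverse=True, return_counts=True)
    except TypeError as exc:  # mixed incomparable types in an object array
        raise ValueError(f"outcome values are not mutually orderable: {exc}") from exc
    return UniqueOutcomeIndex(
        unique_values=uniq, counts=counts, obs_rank=inverse.astype(np.intp)
    )


# ---------------------------------------------------------------------------
# link functions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LinkFunction:
    """A link G: (0,1) -> R with inverse G^{-1} = F_eps and its density.

    ``g_inv`` is the CDF of the latent error; ``g_inv_deriv`` its density.
    Both accept +/-inf and return the correct limits (1/0 and 0).
    """

    name: str
    g: Callable[[np.ndarray], np.ndarray]
    g_inv: Callable[[np.ndarray], np.ndarray]
    g_inv_deriv: Callable[[np.ndarray], np.ndarray]


_SQRT_2PI = np.sqrt(2.0 * np.pi)


def _normal_pdf(x):
    x = np.asarray(x, dtype=float)
    with np.errstate(over="ignore"):
        return np.exp(-0.5 * x * x) / _SQRT_2PI


def _logistic_pdf(x):
    p = special.expit(np.asarray(x, dtype=float))
    return p * (1.0 - p)


def _gumbel_min_cdf(x):
    # F_eps for the loglog link G(p) = -log(-log p): F(x) = exp(-exp(-x))
    x = np.asarray(x, dtype=float)
    with np.errstate(over="ignore"):
        return np.exp(-np.exp(-x))


def _gumbel_min_pdf(x):
    x = np.asarray(x, dtype=float)
    with np.errstate(over="ignore", invalid="ignore"):
        t = np.exp(-x)
        out = t * np.exp(-t)
    return np.where(np.isfinite(t), out, 0.0)


def _loglog_link(p):
    p = np.asarray(p, dtype=float)
    return -np.log(-np.log(p))


_LINKS = {
    "probit": LinkFunction("probit", special.ndtri, special.ndtr, _normal_pdf),
    "logit": LinkFunction("logit", special.logit, special.expit, _logistic_pdf),
    "loglog": LinkFunction("loglog", _loglog_link, _gumbel_min_cdf, _gumbel_min_pdf),
}


def make_link(name: str) -> LinkFunction:
    """Return a registered link function.

    ``probit`` pairs with standard-normal errors, ``logit`` with logistic
    errors, and ``loglog`` (G(p) = -log(-log p) applied to P(Y <= y)) with
    extreme-value errors.
    """
    if isinstance(name, LinkFunction):
        return name
    try:
        return _LINKS[name]
    except KeyError:
        raise ValueError(
            f"unknown link {name!r}; supported links: {sorted(_LINKS)}"
        ) from None


# ---------------------------------------------------------------------------
# design container
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CPMDesign:
    """Covariate matrix, optional treatment indicator, and outcome index.

    ``A`` may be None for fits without a treatment term (e.g. the null model
    whose fitted CDF is the empirical CDF).
    """

    X: np.ndarray  # (n, p), p >= 0
    A: Optional[np.ndarray]  # (n,) in {0,1}, or None
    outcome_index: UniqueOutcomeIndex

    def __post_init__(self):
        n = self.outcome_index.n_obs
        X = np.asarray(self.X, dtype=float)
        if X.ndim != 2 or X.shape[0] != n:
            raise ValueError(f"X must be ({n}, p); got shape {np.shape(self.X)}")
        if not np.isfinite(X).all():
            raise ValueError("X contains non-finite entries")
        object.__setattr__(self, "X", X)
        if self.A is not None:
            A = np.asarray(self.A, dtype=float)
            if A.shape != (n,):
                raise ValueError(f"A must have shape ({n},)")
            if not np.isin(A, (0.0, 1.0)).all():
                raise ValueError("treatment indicator must be binary 0/1")
            object.__setattr__(self, "A", A)

    @property
    def n_obs(self) -> int:
        return self.outcome_index.n_obs

    @property
    def n_covariates(self) -> int:
        return int(self.X.shape[1])


def build_design(y, a=None, x=None) -> CPMDesign:
    """Assemble a :class:`CPMDesign` from raw columns.

    ``x`` may be None (no covariates), a 1-d vector (single covariate), or an
    (n, p) matrix.
    """
    index = index_outcomes(y)
    n = index.n_obs
    if x is None:
        X = np.empty((n, 0))
    else:
        X = np.asarray(x, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
    A = None if a is None else np.asarray(a, dtype=float)
    return CPMDesign(X=X, A=A, outcome_index=index)


# ---------------------------------------------------------------------------
# fit result
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CPMFit:
    """NPMLE of a cumulative probability model.

    ``alpha`` holds the J-1 finite intercepts (conceptually alpha_0 = -inf,
    alpha_J = +inf).  ``gradient_norm`` is the max-norm of the gradient in the
    optimizer's parameterization at the returned solution.
    """

    alpha: np.ndarray
    beta: np.ndarray
    tau: float
    link: LinkFunction
    loglik: float
    converged: bool
    n_iter: int
    gradient_norm: float
    outcome_index: UniqueOutcomeIndex
    message: str = ""

    @property
    def has_treatment(self) -> bool:
        return not np.isnan(self.tau)


@dataclass(frozen=True)
class FitOptions:
    """Optimizer controls for :func:`fit_cpm`.

    ``ftol`` is the relative log-likelihood change tolerance, ``gtol`` the
    projected-gradient max-norm tolerance of the quasi-Newton iteration.
    """

    maxiter: int = 1000
    ftol: float = 1e-11
    gtol: float = 1e-6


# ---------------------------------------------------------------------------
# likelihood
# ---------------------------------------------------------------------------

def _cell_terms(alpha: np.ndarray, eta: np.ndarray, ranks: np.ndarray, link: LinkFunction):
    """Per-observation cell probabilities and boundary densities.

    Observation i with unique-value rank r contributes
    p_i = F(alpha_{r+1} - eta_i) - F(alpha_r - eta_i), with alpha_0 = -inf and
    alpha_J = +inf handled through a padded threshold vector.
    """
    alpha_ext = np.concatenate(([-np.inf], alpha, [np.inf]))
    u_hi = alpha_ext[ranks + 1] - eta
    u_lo = alpha_ext[ranks] - eta
    F_hi = link.g_inv(u_hi)
    F_lo = link.g_inv(u_lo)
    p = F_hi - F_lo
    f_hi = link.g_inv_deriv(u_hi)
    f_lo = link.g_inv_deriv(u_lo)
    return p, f_hi, f_lo


def cpm_negative_loglik(alpha, beta, tau, design: CPMDesign, link: LinkFunction):
    """Negative log-likelihood and its gradient in (alpha, beta, tau).

    Returns ``(nll, grad)`` with ``grad`` the concatenation of the alpha,
    beta and (when the design has a treatment column) tau components.  A
    non-increasing ``alpha`` or a cell probability at the clipping floor
    yields ``nll = +inf`` (the optimizer treats the point as infeasible).
    """
    alpha = np.atleast_1d(np.asarray(alpha, dtype=float))
    beta = np.atleast_1d(np.asarray(beta, dtype=float))
    ranks = design.outcome_index.obs_rank
    if alpha.size and np.any(np.diff(alpha) <= 0):
        return np.inf, np.full(alpha.size + beta.size + (design.A is not None), np.nan)
    eta = design.X @ beta
    if design.A is not None:
        eta = eta + float(tau) * design.A
    p, f_hi, f_lo = _cell_terms(alpha, eta, ranks, link)
    floored = p <= PROB_FLOOR
    p_safe = np.maximum(p, PROB_FLOOR)
    nll = -float(np.sum(np.log(p_safe)))
    w = 1.0 / p_safe
    d_eta = (f_hi - f_lo) * w  # d(-log p_i)/d eta_i
    J = design.outcome_index.n_unique
    grad_alpha = np.zeros(J - 1) if J > 1 else np.zeros(0)
    if J > 1:
        hi_mask = ranks <= J - 2
        lo_mask = ranks >= 1
        np.add.at(grad_alpha, ranks[hi_mask], -(f_hi * w)[hi_mask])
        np.add.at(grad_alpha, ranks[lo_mask] - 1, (f_lo * w)[lo_mask])
    grad = [grad_alpha, design.X.T @ d_eta]
    if design.A is not None:
        grad.append([design.A @ d_eta])
    grad = np.concatenate(grad)
    if floored.any():
        nll = np.inf
    return nll, grad


def _make_objective(design: CPMDesign, link: LinkFunction):
    """Objective in the monotone parameterization.

    Parameter vector: (alpha_1, log diffs d_2..d_{J-1}, beta, tau).  Gradient
    chain rule: d/d alpha_1 = sum_k g_alpha_k; d/d d_j = exp(d_j) *
    sum_{k >= j} g_alpha_k.
    """
    index = design.outcome_index
    J = index.n_unique
    ranks = index.obs_rank
    n_coef = design.n_covariates + (design.A is not None)
    Z_parts = [design.X]
    if design.A is not None:
        Z_parts.append(design.A[:, None])
    Z = np.hstack(Z_parts) if n_coef else np.empty((index.n_obs, 0))
    # per-rank aggregation via bincount is the hot path; precompute masks
    hi_mask = ranks <= J - 2
    lo_mask = ranks >= 1
    hi_idx = ranks[hi_mask]
    lo_idx = ranks[lo_mask] - 1

    def unpack(theta):
        a = theta[: J - 1]
        if J > 2:
            alpha = np.concatenate(([a[0]], a[0] + np.cumsum(np.exp(a[1:]))))
        else:
            alpha = a[:1].copy()
        coef = theta[J - 1:]
        return alpha, coef

    def objective(theta):
        alpha, coef = unpack(theta)
        eta = Z @ coef if n_coef else np.zeros(index.n_obs)
        p, f_hi, f_lo = _cell_terms(alpha, eta, ranks, link)
        p_safe = np.maximum(p, PROB_FLOOR)
        nll = -float(np.sum(np.log(p_safe)))
        w = 1.0 / p_safe
        grad_alpha = np.zeros(J - 1)
        grad_alpha += np.bincount(hi_idx, weights=-(f_hi * w)[hi_mask], minlength=J - 1)
        grad_alpha += np.bincount(lo_idx, weights=(f_lo * w)[lo_mask], minlength=J - 1)
        # chain rule into (alpha_1, log-diff) coordinates
        tail = np.cumsum(grad_alpha[::-1])[::-1]
        g = np.empty_like(theta)
        g[0] = tail[0]
        if J > 2:
            g[1: J - 1] = np.exp(theta[1: J - 1]) * tail[1:]
        if n_coef:
            d_eta = (f_hi - f_lo) * w
            g[J - 1:] = Z.T @ d_eta
        return nll, g

    def floor_active(theta):
        alpha, coef = unpack(theta)
        eta = Z @ coef if n_coef else np.zeros(index.n_obs)
        p, _, _ = _cell_terms(alpha, eta, ranks, link)
        return bool((p <= PROB_FLOOR).any())

    return objective, unpack, floor_active


def _initial_parameters(design: CPMDesign, link: LinkFunction) -> np.ndarray:
    """Link-transformed empirical CDF for alpha; zero coefficients.

    This is the exact NPMLE of the null model, and a good basin otherwise.
    """
    index = design.outcome_index
    n = index.n_obs
    J = index.n_unique
    ecdf = np.cumsum(index.counts[: J - 1]) / n
    ecdf = np.clip(ecdf, 1.0 / (n + 1), n / (n + 1.0))
    alpha0 = np.asarray(link.g(ecdf), dtype=float)
    if J > 2:
        d0 = np.log(np.maximum(np.diff(alpha0), 1e-8))
        head = np.concatenate(([alpha0[0]], d0))
    else:
        head = alpha0[:1]
    n_coef = design.n_covariates + (design.A is not None)
    return np.concatenate([head, np.zeros(n_coef)])


def fit_cpm(design: CPMDesign, link="probit", options: FitOptions | None = None) -> CPMFit:
    """Fit the CPM by nonparametric maximum likelihood.

    Uses an analytic-gradient quasi-Newton (L-BFGS-B) iteration on the
    monotone intercept parameterization, started from the link-transformed
    empirical CDF.  Non-convergence is reported through ``converged=False``
    and the diagnostics fields — never an exception — so that batch callers
    (simulations, bootstrap) can account for failures as data.
    """
    link = make_link(link)
    options = options or FitOptions()
    index = design.outcome_index
    J = index.n_unique
    p = design.n_covariates
    tau_nan = np.nan if design.A is None else 0.0

    if J == 1:
        # degenerate support: the single cell spans (-inf, inf), likelihood 1
        return CPMFit(
            alpha=np.zeros(0), beta=np.zeros(p), tau=tau_nan, link=link,
            loglik=0.0, converged=True, n_iter=0, gradient_norm=0.0,
            outcome_index=index, message="degenerate single-valued outcome",
        )

    objective, unpack, floor_active = _make_objective(design, link)
    theta0 = _initial_parameters(design, link)
    res = optimize.minimize(
        objective,
        theta0,
        jac=True,
        method="L-BFGS-B",
        options={
            "maxiter": options.maxiter,
            "maxfun": 20 * options.maxiter,
            "ftol": options.ftol,
            "gtol": options.gtol,
        },
    )
    alpha, coef = unpack(res.x)
    nll, grad = objective(res.x)
    floored = floor_active(res.x)
    converged = bool(res.success) and not floored and np.isfinite(nll)
    beta = coef[:p]
    tau = float(coef[p]) if design.A is not None else np.nan
    return CPMFit(
        alpha=alpha,
        beta=beta,
        tau=tau,
        link=link,
        loglik=-nll,
        converged=converged,
        n_iter=int(res.nit),
        gradient_norm=float(np.max(np.abs(grad))) if grad.size else 0.0,
        outcome_index=index,
        message=str(res.message) + (" [probability floor active]" if floored else ""),
    )


# ---------------------------------------------------------------------------
# fitted-model evaluation
# ---------------------------------------------------------------------------

def alpha_step(fit: CPMFit, y) -> np.ndarray | float:
    """Evaluate the fitted step intercept function at ``y``.

    Returns alpha_k for the largest unique value y_(k) <= y, -inf below the
    support, and +inf at or above the largest observed value.
    """
    vals = fit.outcome_index.unique_values
    y_arr = np.asarray(y)
    k = np.searchsorted(vals, y_arr, side="right")  # number of unique values <= y
    alpha_ext = np.concatenate(([-np.inf], fit.alpha, [np.inf]))
    out = alpha_ext[k]
    return float(out) if np.isscalar(y) or y_arr.ndim == 0 else out


def conditional_cdf(fit: CPMFit, y, x=None, a=0.0):
    """Fitted conditional CDF P(Y <= y | X = x, A = a)."""
    p = fit.beta.shape[0]
    if x is None:
        x = np.zeros(p)
    x = np.atleast_1d(np.asarray(x, dtype=float))
    if x.shape != (p,):
        raise ValueError(f"x must have length {p}; got shape {x.shape}")
    eta = float(fit.beta @ x)
    if fit.has_treatment:
        eta += fit.tau * float(a)
    u = np.asarray(alpha_step(fit, y), dtype=float) - eta
    out = fit.link.g_inv(u)
    return float(out) if np.isscalar(y) else out
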