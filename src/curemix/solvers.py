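"""Weighted, L1-penalized M-step solvers.

Two coordinate-descent solvers back the EM M-steps:

* a fractional-response logistic LASSO (response = posterior susceptibility
  weight in [0, 1], intercept unpenalized), fitted by IRLS with
  coordinate-wise soft-thresholding;
* a case-weighted Cox partial-likelihood LASSO with Breslow tie handling,
  fitted by a proximal-Newton scheme with a diagonal Hessian approximation.

Both solvers standardize columns internally (the L1 penalty is applied on
the standardized scale) and report coefficients on the original scale; both
use step-halving so the penalized objective never decreases across outer
iterations, and both check stationarity (KKT) conditions before declaring
convergence.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from numba import njit
from scipy.special import expit

_IRLS_WEIGHT_FLOOR = 1e-5  # working-weight floor; avoids divergence at p near 0/1
_KKT_TOL = 1e-6


class ConvergenceWarning(UserWarning):
    pass


@dataclass
class PenaltyConfig:
    """Penalty levels and solver controls.

    ``tolerance``/``max_iterations`` govern the coordinate-descent solvers
    (max absolute coefficient change per outer iteration);
    ``em_tolerance``/``em_max_iterations`` govern the outer EM loop.
    """

    lambda_incidence: float = 0.0
    lambda_latency: float = 0.0
    standardize: bool = True
    max_iterations: int = 200
    tolerance: float = 1e-8
    active_set: bool = True
    em_tolerance: float = 1e-4
    em_max_iterations: int = 100

    def __post_init__(self) -> None:
        if self.lambda_incidence < 0 or self.lambda_latency < 0:
            raise ValueError("penalty levels must be non-negative")
        if self.tolerance <= 0 or self.em_tolerance <= 0:
            raise ValueError("tolerances must be positive")
        if self.max_iterations < 1 or self.em_max_iterations < 1:
            raise ValueError("iteration limits must be >= 1")


@dataclass
class LogisticFit:
    intercept: float
    coefficients: np.ndarray
    converged: bool
    n_iter: int
    kkt_residual: float

    def __iter__(self):  # allows ``intercept, coef = fit`` unpacking
        return iter((self.intercept, self.coefficients))


@dataclass
class CoxFit:
    coefficients: np.ndarray
    converged: bool
    n_iter: int
    kkt_residual: float


def soft_threshold(a: float, gamma: float) -> float:
    """S(a, gamma) = sign(a) * max(|a| - gamma, 0)."""
    return np.sign(a) * max(abs(a) - gamma, 0.0)


@njit(cache=False)
def _cd_pass(X, v, r, b, xv2, lam, js):
    """One coordinate-descent pass over columns ``js`` of the weighted
    least-squares problem  min 1/2 sum v_i r_i^2 + lam * sum |b_j|,
    maintaining the residual r in place.  Returns max |delta b|."""
    n = X.shape[0]
    maxc = 0.0
    for k in range(js.shape[0]):
        j = js[k]
        if xv2[j] <= 0.0:
            continue
        a = 0.0
        for i in range(n):
            a += v[i] * X[i, j] * r[i]
        a += xv2[j] * b[j]
        if a > lam:
            bn = (a - lam) / xv2[j]
        elif a < -lam:
            bn = (a + lam) / xv2[j]
        else:
            bn = 0.0
        d = bn - b[j]
        if d != 0.0:
            for i in range(n):
                r[i] -= d * X[i, j]
            b[j] = bn
            if abs(d) > maxc:
                maxc = abs(d)
    return maxc


@njit(cache=False)
def _intercept_pass(v, r, sv):
    n = r.shape[0]
    s = 0.0
    for i in range(n):
        s += v[i] * r[i]
    d = s / sv
    for i in range(n):
        r[i] -= d
    return d


def _solve_quadratic(
    X, v, r, b, lam, tol, use_active_set, fit_intercept, sv, max_full_sweeps=5, max_active_sweeps=50
):
    """Approximately solve the penalized weighted least-squares subproblem.

    ``r`` holds the current residual (working response minus linear
    predictor) and is updated in place along with ``b``.  The subproblem is
    solved inexactly (a few full sweeps, each followed by active-set
    cycling): the outer proximal-Newton loop owns convergence, so exact
    inner solves would be wasted work.  Returns the accumulated intercept
    shift.
    """
    p = X.shape[1]
    xv2 = np.einsum("ij,ij->j", X * v[:, None], X)
    all_js = np.arange(p, dtype=np.int64)
    b0_shift = 0.0
    inner_tol = max(tol, 1e-12)
    for _ in range(max_full_sweeps):
        if fit_intercept:
            b0_shift += _intercept_pass(v, r, sv)
        change = _cd_pass(X, v, r, b, xv2, lam, all_js)
        if use_active_set:
            active = np.flatnonzero(b)
            for _ in range(max_active_sweeps):
                if active.size == 0:
                    break
                if fit_intercept:
                    b0_shift += _intercept_pass(v, r, sv)
                c = _cd_pass(X, v, r, b, xv2, lam, active.astype(np.int64))
                if c < inner_tol:
                    break
        if change < inner_tol:
            break
    return b0_shift


def _standardize(X, standardize):
    mean = X.mean(axis=0) if standardize else np.zeros(X.shape[1])
    if standardize:
        std = X.std(axis=0)
        std = np.where(std < 1e-12, 1.0, std)
    else:
        std = np.ones(X.shape[1])
    Xs = (X - mean) / std if standardize else np.asarray(X, dtype=float)
    return np.ascontiguousarray(Xs), mean, std


def _logistic_objective(eta, response, b, lam):
    # sum w*eta - log(1 + e^eta) - lam * ||b||_1, numerically stable
    return float(np.sum(response * eta - np.logaddexp(0.0, eta)) - lam * np.abs(b).sum())


def _kkt_residual(grad, b, lam):
    """Max violation of the stationarity conditions of an L1 problem."""
    nz = b != 0
    res = 0.0
    if np.any(nz):
        res = np.max(np.abs(grad[nz] - lam * np.sign(b[nz])))
    if np.any(~nz):
        res = max(res, float(np.max(np.maximum(np.abs(grad[~nz]) - lam, 0.0))))
    return float(res)


def lambda_max_logistic(X, response, standardize=True) -> float:
    """Smallest penalty that shrinks every slope to zero (intercept kept)."""
    Xs, _, _ = _standardize(np.asarray(X, dtype=float), standardize)
    w = np.asarray(response, dtype=float)
    g = Xs.T @ (w - w.mean())
    return float(np.max(np.abs(g))) if g.size else 0.0


def fit_weighted_lasso_logistic(
    X,
    response,
    lam: float,
    init: np.ndarray | None = None,
    init_intercept: float = 0.0,
    config: PenaltyConfig | None = None,
) -> LogisticFit:
    """Maximize sum_i [w_i log pi_i + (1-w_i) log(1-pi_i)] - lam * ||b||_1.

    ``response`` may be fractional (E-step weights).  The intercept is never
    penalized.  Coefficients are returned on the original covariate scale.
    """
    config = config or PenaltyConfig()
    X = np.asarray(X, dtype=float)
    response = np.asarray(response, dtype=float)
    if not np.all(np.isfinite(X)):
        raise ValueError("covariate matrix contains non-finite values")
    if np.any(response < -1e-12) or np.any(response > 1 + 1e-12):
        raise ValueError("response must lie in [0, 1]")
    response = np.clip(response, 0.0, 1.0)
    n, p = X.shape
    Xs, mean, std = _standardize(X, config.standardize)

    b = np.zeros(p)
    b0 = float(init_intercept)
    if init is not None:
        init = np.asarray(init, dtype=float)
        b = init * std  # to standardized scale
        b0 = float(init_intercept + mean @ init)

    eta = b0 + Xs @ b
    obj = _logistic_objective(eta, response, b, lam)
    converged = False
    it = 0
    for it in range(1, config.max_iterations + 1):
        pr = expit(eta)
        v = np.maximum(pr * (1.0 - pr), _IRLS_WEIGHT_FLOOR)
        sv = v.sum()
        r = (response - pr) / v  # residual of working response about eta
        b_old = b.copy()
        b0_old = b0
        b0 += _solve_quadratic(Xs, v, r, b, lam, config.tolerance, config.active_set, True, sv)
        eta = b0 + Xs @ b
        new_obj = _logistic_objective(eta, response, b, lam)
        halvings = 0
        while new_obj < obj - 1e-12 and halvings < 30:
            b = 0.5 * (b + b_old)
            b0 = 0.5 * (b0 + b0_old)
            eta = b0 + Xs @ b
            new_obj = _logistic_objective(eta, response, b, lam)
            halvings += 1
        obj = max(obj, new_obj)
        change = max(abs(b0 - b0_old), float(np.max(np.abs(b - b_old))) if p else 0.0)
        if change < config.tolerance:
            grad = Xs.T @ (response - expit(eta))
            if p == 0 or _kkt_residual(grad, b, lam) < _KKT_TOL:
                converged = True
                break
    grad = Xs.T @ (response - expit(eta))
    kkt = _kkt_residual(grad, b, lam) if p else 0.0
    if not converged:
        warnings.warn(
            f"logistic LASSO did not converge in {config.max_iterations} iterations "
            f"(KKT residual {kkt:.2e})",
            ConvergenceWarning,
        )
    coef = b / std
    intercept = b0 - mean @ coef
    return LogisticFit(float(intercept), coef, converged, it, kkt)


def _cox_sufficients(times, events, case_weights):
    """Sort by time; precompute tie-group bookkeeping for Breslow risk sets."""
    order = np.argsort(times, kind="stable")
    t = times[order]
    e = events[order]
    uniq, first_idx = np.unique(t, return_index=True)
    d = np.add.reduceat(e, first_idx)  # events per tie group
    group_of = np.searchsorted(uniq, t)
    return order, t, e, uniq, first_idx, d, group_of


def _cox_grad_hess(eta_sorted, e_sorted, w_sorted, first_idx, d, group_of):
    """Per-sample gradient and diagonal Hessian of the weighted partial
    log-likelihood, plus its value; all on the time-sorted arrays."""
    we = w_sorted * np.exp(eta_sorted)
    suffix = np.cumsum(we[::-1])[::-1]
    denom = suffix[first_idx]  # risk-set mass per tie group
    has_event = d > 0
    if np.any(denom[has_event] <= 0):
        bad = np.asarray(first_idx)[has_event][denom[has_event] <= 0]
        raise FloatingPointError(f"zero risk-set mass at event time index {bad.tolist()}")
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio1 = np.where(denom > 0, d / denom, 0.0)
        ratio2 = np.where(denom > 0, d / denom**2, 0.0)
    A = np.cumsum(ratio1)[group_of]  # sum over event groups with t_k <= t_i
    B = np.cumsum(ratio2)[group_of]
    g = e_sorted - we * A
    h = we * A - we**2 * B
    pl = float(np.sum(e_sorted * eta_sorted) - np.sum(d[has_event] * np.log(denom[has_event])))
    return g, h, pl


def lambda_max_cox(Z, times, events, case_weights, standardize=True) -> float:
    """Smallest penalty shrinking all latency coefficients to zero."""
    Z = np.asarray(Z, dtype=float)
    if Z.shape[1] == 0:
        return 0.0
    Zs, _, _ = _standardize(Z, standardize)
    order, t, e, uniq, first_idx, d, group_of = _cox_sufficients(
        np.asarray(times, float), np.asarray(events), np.asarray(case_weights, float)
    )
    g, _, _ = _cox_grad_hess(
        np.zeros(len(t)), e, np.asarray(case_weights, float)[order], first_idx, d, group_of
    )
    grad = Zs[order].T @ g
    return float(np.max(np.abs(grad)))


def fit_weighted_lasso_cox(
    Z,
    times,
    events,
    case_weights,
    lam: float,
    init: np.ndarray | None = None,
    config: PenaltyConfig | None = None,
) -> CoxFit:
    """Maximize the case-weighted Cox partial log-likelihood minus lam*||beta||_1.

    Objective: sum_i delta_i [z_i'beta - log sum_{j: t_j >= t_i} w_j e^{z_j'beta}]
    with Breslow tie handling.  Events must carry weight 1; censored samples
    enter only through the weighted risk sets.
    """
    config = config or PenaltyConfig()
    Z = np.asarray(Z, dtype=float)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events).astype(int)
    case_weights = np.asarray(case_weights, dtype=float)
    if not np.all(np.isfinite(Z)):
        raise ValueError("covariate matrix contains non-finite values")
    if events.sum() < 1:
        raise ValueError("Cox fit requires at least one event")
    if np.any(np.abs(case_weights[events == 1] - 1.0) > 1e-9):
        raise ValueError("events must have case weight 1")
    n, p = Z.shape
    if p == 0:
        return CoxFit(np.zeros(0), True, 0, 0.0)
    Zs, mean, std = _standardize(Z, config.standardize)

    order, t, e_sorted, uniq, first_idx, d, group_of = _cox_sufficients(times, events, case_weights)
    Zso = np.ascontiguousarray(Zs[order])
    w_sorted = case_weights[order]

    b = np.asarray(init, dtype=float) * std if init is not None else np.zeros(p)
    eta = Zso @ b
    g, h, pl = _cox_grad_hess(eta, e_sorted, w_sorted, first_idx, d, group_of)
    obj = pl - lam * np.abs(b).sum()
    converged = False
    it = 0
    for it in range(1, config.max_iterations + 1):
        v = np.maximum(h, _IRLS_WEIGHT_FLOOR)
        r = g / v
        b_old = b.copy()
        _solve_quadratic(Zso, v, r, b, lam, config.tolerance, config.active_set, False, v.sum())
        eta = Zso @ b
        g, h, pl = _cox_grad_hess(eta, e_sorted, w_sorted, first_idx, d, group_of)
        new_obj = pl - lam * np.abs(b).sum()
        halvings = 0
        while new_obj < obj - 1e-12 and halvings < 30:
            b = 0.5 * (b + b_old)
            eta = Zso @ b
            g, h, pl = _cox_grad_hess(eta, e_sorted, w_sorted, first_idx, d, group_of)
            new_obj = pl - lam * np.abs(b).sum()
            halvings += 1
        obj = max(obj, new_obj)
        change = float(np.max(np.abs(b - b_old))) if p else 0.0
        if change < config.tolerance:
            if _kkt_residual(Zso.T @ g, b, lam) < _KKT_TOL:
                converged = True
                break
    kkt = _kkt_residual(Zso.T @ g, b, lam)
    if not converged:
        warnings.warn(
            f"Cox LASSO did not converge in {config.max_iterations} iterations "
            f"(KKT residual {kkt:.2e})",
            ConvergenceWarning,
        )
    return CoxFit(b / std, converged, it, kkt)
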