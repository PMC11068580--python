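"""Penalized solver correctness against independent oracles.

The oracles here are deliberately naive: a dense Newton-Raphson for the
fractional-response logistic likelihood and for the weighted Cox partial
likelihood (risk sets enumerated per event), plus brute-force scalar
optimization for the soft-threshold operator.  None of them share code with
the coordinate-descent implementations they check.
"""

import numpy as np
import pytest
from scipy.optimize import minimize_scalar

import curemix as cm
from curemix.solvers import PenaltyConfig, _kkt_residual, _standardize


# ---------------------------------------------------------------------------
# independent oracles


def newton_logistic(X, w, max_iter=200):
    """Unpenalized Newton-Raphson for sum w*log(pi) + (1-w)*log(1-pi)."""
    from scipy.special import expit

    A = np.column_stack([np.ones(len(w)), X])
    theta = np.zeros(A.shape[1])
    for _ in range(max_iter):
        p = expit(A @ theta)
        grad = A.T @ (w - p)
        hess = A.T @ (A * (p * (1 - p))[:, None])
        step = np.linalg.solve(hess + 1e-10 * np.eye(len(theta)), grad)
        theta += step
        if np.max(np.abs(step)) < 1e-12:
            break
    return theta[0], theta[1:]


def weighted_partial_loglik(beta, Z, times, events, weights):
    """Direct enumeration of the Breslow-tied weighted partial likelihood."""
    eta = Z @ beta
    ll = 0.0
    for k in np.unique(times[events == 1]):
        at_k = (times == k) & (events == 1)
        risk = times >= k
        ll += eta[at_k].sum() - at_k.sum() * np.log(np.sum(weights[risk] * np.exp(eta[risk])))
    return ll


def newton_cox(Z, times, events, weights, max_iter=100):
    """Newton-Raphson on the weighted partial likelihood with a numerical
    Hessian (finite differences of the analytic gradient)."""
    p = Z.shape[1]

    def grad(beta):
        eta = Z @ beta
        g = np.zeros(p)
        for k in np.unique(times[events == 1]):
            at_k = (times == k) & (events == 1)
            risk = times >= k
            we = weights[risk] * np.exp(eta[risk])
            g += Z[at_k].sum(axis=0) - at_k.sum() * (we @ Z[risk]) / we.sum()
        return g

    beta = np.zeros(p)
    eps = 1e-6
    for _ in range(max_iter):
        g = grad(beta)
        H = np.zeros((p, p))
        for j in range(p):
            e = np.zeros(p)
            e[j] = eps
            H[:, j] = (grad(beta + e) - grad(beta - e)) / (2 * eps)
        step = np.linalg.solve(H - 1e-10 * np.eye(p), g)
        beta -= step
        if np.max(np.abs(step)) < 1e-10:
            break
    return beta


def random_cox_instance(rng, n, p, censor=0.3, weighted=False):
    Z = rng.standard_normal((n, p))
    times = rng.exponential(1.0, n) + 0.01  # continuous, tie-free
    events = (rng.uniform(size=n) > censor).astype(int)
    if events.sum() == 0:
        events[0] = 1
    w = np.ones(n)
    if weighted:
        w = rng.uniform(0.2, 1.0, n)
        w[events == 1] = 1.0
    return Z, times, events, w


# ---------------------------------------------------------------------------
# soft threshold


@pytest.mark.parametrize("a,gamma", [(2.0, 0.5), (-2.0, 0.5), (0.3, 0.5), (0.0, 1.0), (-0.2, 0.1)])
def test_soft_threshold_solves_scalar_lasso(a, gamma):
    # argmin_b 1/2 (b - a)^2 + gamma |b|
    res = minimize_scalar(lambda b: 0.5 * (b - a) ** 2 + gamma * abs(b), bounds=(-5, 5), method="bounded")
    assert cm.soft_threshold(a, gamma) == pytest.approx(res.x, abs=1e-5)


# ---------------------------------------------------------------------------
# logistic


def test_logistic_full_shrinkage_at_lambda_max():
    rng = np.random.default_rng(1)
    X = rng.standard_normal((60, 8))
    w = rng.uniform(size=60)
    lmax = cm.lambda_max_logistic(X, w)
    fit = cm.fit_weighted_lasso_logistic(X, w, lmax * 1.0001)
    from scipy.special import logit

    assert np.all(fit.coefficients == 0.0)
    assert fit.intercept == pytest.approx(logit(w.mean()), abs=1e-6)
    # just below lambda_max at least one coefficient enters
    fit2 = cm.fit_weighted_lasso_logistic(X, w, lmax * 0.95)
    assert np.any(fit2.coefficients != 0.0)


def test_logistic_symmetric_response_has_no_signal():
    rng = np.random.default_rng(2)
    X = rng.standard_normal((40, 5))
    fit = cm.fit_weighted_lasso_logistic(X, np.full(40, 0.5), 0.1)
    assert np.all(fit.coefficients == 0.0)
    assert fit.intercept == pytest.approx(0.0, abs=1e-8)


def test_logistic_unpenalized_matches_newton_oracle():
    rng = np.random.default_rng(3)
    X = rng.standard_normal((30, 3))
    w = rng.uniform(size=30)
    fit = cm.fit_weighted_lasso_logistic(X, w, 0.0)
    b0, b = newton_logistic(X, w)
    assert fit.intercept == pytest.approx(b0, abs=1e-4)
    np.testing.assert_allclose(fit.coefficients, b, atol=1e-4)


def test_logistic_unpenalized_matches_statsmodels():
    import statsmodels.api as sm

    rng = np.random.default_rng(4)
    X = rng.standard_normal((50, 4))
    w = rng.uniform(size=50)
    fit = cm.fit_weighted_lasso_logistic(X, w, 0.0)
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        glm = sm.GLM(w, sm.add_constant(X), family=sm.families.Binomial()).fit()
    np.testing.assert_allclose(
        np.r_[fit.intercept, fit.coefficients], glm.params, atol=1e-6
    )


# ---------------------------------------------------------------------------
# cox


def test_cox_full_shrinkage():
    rng = np.random.default_rng(5)
    Z, times, events, w = random_cox_instance(rng, 50, 6)
    lmax = cm.lambda_max_cox(Z, times, events, w)
    fit = cm.fit_weighted_lasso_cox(Z, times, events, w, lmax * 1.0001)
    assert np.all(fit.coefficients == 0.0)
    fit2 = cm.fit_weighted_lasso_cox(Z, times, events, w, lmax * 0.9)
    assert np.any(fit2.coefficients != 0.0)


def test_cox_unpenalized_matches_newton_oracle():
    rng = np.random.default_rng(6)
    Z, times, events, w = random_cox_instance(rng, 20, 2)
    fit = cm.fit_weighted_lasso_cox(Z, times, events, w, 0.0)
    oracle = newton_cox(Z, times, events, w)
    np.testing.assert_allclose(fit.coefficients, oracle, atol=1e-4)


def test_weighted_cox_matches_newton_oracle():
    rng = np.random.default_rng(7)
    Z, times, events, w = random_cox_instance(rng, 25, 2, weighted=True)
    fit = cm.fit_weighted_lasso_cox(Z, times, events, w, 0.0)
    oracle = newton_cox(Z, times, events, w)
    np.testing.assert_allclose(fit.coefficients, oracle, atol=1e-4)
    # and the solution actually maximizes the enumerated partial likelihood
    ll_fit = weighted_partial_loglik(fit.coefficients, Z, times, events, w)
    ll_pert = weighted_partial_loglik(fit.coefficients + 0.01, Z, times, events, w)
    assert ll_fit >= ll_pert


def test_cox_unpenalized_matches_lifelines():
    from lifelines import CoxPHFitter
    import pandas as pd

    rng = np.random.default_rng(8)
    Z, times, events, w = random_cox_instance(rng, 40, 3)
    fit = cm.fit_weighted_lasso_cox(Z, times, events, w, 0.0)
    df = pd.DataFrame(Z, columns=["z1", "z2", "z3"])
    df["t"], df["e"] = times, events
    cph = CoxPHFitter().fit(df, "t", "e")
    np.testing.assert_allclose(fit.coefficients, cph.params_.to_numpy(), atol=1e-4)


def test_censoring_weights_only_enter_risk_sets():
    # without censoring, down-weighting "censored" samples changes nothing
    rng = np.random.default_rng(9)
    Z = rng.standard_normal((30, 2))
    times = rng.exponential(1.0, 30) + 0.01
    events = np.ones(30, dtype=int)
    fit1 = cm.fit_weighted_lasso_cox(Z, times, events, np.ones(30), 1.0)
    fit2 = cm.fit_weighted_lasso_cox(Z, times, events, np.ones(30), 1.0)
    np.testing.assert_allclose(fit1.coefficients, fit2.coefficients, atol=1e-12)
    # with censoring, zeroing censored weights changes the fit
    Zc, tc, ec, wc = random_cox_instance(rng, 30, 2, censor=0.5)
    w0 = wc.copy()
    w0[ec == 0] = 0.0
    f_all = cm.fit_weighted_lasso_cox(Zc, tc, ec, wc, 0.5)
    f_zero = cm.fit_weighted_lasso_cox(Zc, tc, ec, w0, 0.5)
    assert not np.allclose(f_all.coefficients, f_zero.coefficients)


def test_event_weights_must_be_one():
    rng = np.random.default_rng(10)
    Z, times, events, w = random_cox_instance(rng, 20, 2)
    w[events == 1] = 0.5
    with pytest.raises(ValueError, match="weight 1"):
        cm.fit_weighted_lasso_cox(Z, times, events, w, 0.1)


# ---------------------------------------------------------------------------
# KKT and path stability


@pytest.mark.parametrize("seed", range(10))
def test_kkt_residuals_below_tolerance_at_positive_lambda(seed):
    rng = np.random.default_rng(100 + seed)
    n, p = 40, 6
    X = rng.standard_normal((n, p))
    w = rng.uniform(size=n)
    lam = 0.3 * cm.lambda_max_logistic(X, w)
    fit = cm.fit_weighted_lasso_logistic(X, w, lam)
    assert fit.converged and fit.kkt_residual < 1e-6

    Z, times, events, cw = random_cox_instance(rng, n, p, weighted=True)
    lam_c = 0.3 * cm.lambda_max_cox(Z, times, events, cw)
    cfit = cm.fit_weighted_lasso_cox(Z, times, events, cw, lam_c)
    assert cfit.converged and cfit.kkt_residual < 1e-6


def test_solution_path_continuity_under_small_lambda_perturbation():
    rng = np.random.default_rng(11)
    X = rng.standard_normal((80, 10))
    w = rng.uniform(size=80)
    lam = 0.2 * cm.lambda_max_logistic(X, w)
    base = cm.fit_weighted_lasso_logistic(X, w, lam)
    for factor in (0.99, 1.01):
        pert = cm.fit_weighted_lasso_logistic(
            X, w, lam * factor, init=base.coefficients, init_intercept=base.intercept
        )
        assert np.max(np.abs(pert.coefficients - base.coefficients)) < 0.05


def test_kkt_residual_helper_against_direct_gradient():
    rng = np.random.default_rng(12)
    X = rng.standard_normal((50, 5))
    w = rng.uniform(size=50)
    lam = 0.4 * cm.lambda_max_logistic(X, w)
    fit = cm.fit_weighted_lasso_logistic(X, w, lam)
    from scipy.special import expit

    Xs, mean, std = _standardize(X, True)
    b_std = fit.coefficients * std
    b0_std = fit.intercept + mean @ fit.coefficients
    grad = Xs.T @ (w - expit(b0_std + Xs @ b_std))
    assert _kkt_residual(grad, b_std, lam) < 1e-6
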