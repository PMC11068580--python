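"""EM driver for the penalized semi-parametric mixture cure model.

Each EM iteration alternates

1. E-step: posterior susceptibility weights given current parameters;
2. incidence M-step: fractional-response LASSO logistic regression of the
   weights on expression;
3. latency M-step: case-weighted LASSO Cox partial likelihood (events carry
   weight 1, censored samples enter risk sets with their posterior weight);
4. Breslow refresh of the nonparametric baseline under the new latency
   coefficients and weights.

The penalized observed-data log-likelihood is recorded every iteration; by
the generalized-EM argument (each M-step only improves its own objective
from a warm start, and the Breslow refresh maximizes the baseline part of
the expected complete-data log-likelihood) it is non-decreasing up to
floating-point slack, which is monitored rather than assumed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.special import logit

from .model import (
    MCMParameters,
    SurvivalDataset,
    breslow_baseline,
    e_step,
    observed_loglik,
    susceptibility_probability,
)
from .solvers import (
    PenaltyConfig,
    fit_weighted_lasso_cox,
    fit_weighted_lasso_logistic,
    lambda_max_cox,
    lambda_max_logistic,
)
from .stratify import km_estimate

_INTERCEPT_CAP = 15.0  # |logit| cap; guards divergence when latent classes separate
_ASCENT_SLACK = 1e-8   # relative slack for the monotonicity monitor


class EMWarning(UserWarning):
    pass


@dataclass
class EMTrace:
    """Per-iteration EM bookkeeping."""

    penalized_loglik: List[float] = field(default_factory=list)
    max_param_change: List[float] = field(default_factory=list)
    converged: bool = False

    @property
    def n_iterations(self) -> int:
        return len(self.penalized_loglik)

    def monotone(self, slack: float = _ASCENT_SLACK) -> bool:
        ll = np.asarray(self.penalized_loglik)
        if ll.size < 2:
            return True
        tol = slack * np.maximum(np.abs(ll[:-1]), 1.0)
        return bool(np.all(np.diff(ll) >= -tol))


@dataclass
class FittedMCM:
    """A deployable fitted model: parameters plus the trained decision rule."""

    parameters: MCMParameters
    penalty: PenaltyConfig
    trace: EMTrace
    training_risk_score_cutoff: float
    cure_threshold: float
    gene_names: np.ndarray


def _cap_intercept(b0: float) -> float:
    return float(np.clip(b0, -_INTERCEPT_CAP, _INTERCEPT_CAP))


def initialize(data: SurvivalDataset) -> Tuple[MCMParameters, np.ndarray]:
    """Starting point: KM-based weights, zero coefficients, Breslow baseline.

    Events start at weight 1.  A censored sample at time t starts at
    w = 1 - plateau / S_KM(t), the Kaplan-Meier estimate of
    P(susceptible | T > t) when the final KM value is read as the cure
    fraction: the weight declines toward 0 as follow-up approaches the
    plateau.
    """
    if data.events.sum() < 1:
        raise ValueError("cannot fit a cure model to data with no events")
    km = km_estimate(data.times, data.events)
    plateau = float(km.survival[-1])
    s_at = np.maximum(km.survival_at(data.times), 1e-12)
    w = np.clip(1.0 - plateau / s_at, 0.0, 1.0)
    w[data.events == 1] = 1.0
    p = data.n_genes
    baseline = breslow_baseline(data, w, np.zeros(p))
    params = MCMParameters(
        incidence_intercept=_cap_intercept(logit(np.clip(w.mean(), 1e-12, 1 - 1e-12))),
        incidence_coefficients=np.zeros(p),
        latency_coefficients=np.zeros(p),
        baseline=baseline,
    )
    return params, w


def penalized_observed_loglik(
    params: MCMParameters, data: SurvivalDataset, penalty: PenaltyConfig, column_std=None
) -> float:
    """Observed-data log-likelihood minus the L1 penalties.

    The penalty is evaluated on the same (standardized) scale the solvers
    optimize, so the EM ascent monitor matches the objective actually
    maximized.
    """
    if column_std is None:
        column_std = np.ones(data.n_genes)
    pen = penalty.lambda_incidence * np.abs(params.incidence_coefficients * column_std).sum()
    pen += penalty.lambda_latency * np.abs(params.latency_coefficients * column_std).sum()
    return observed_loglik(params, data) - pen


def em_fit(
    data: SurvivalDataset,
    penalty: PenaltyConfig,
    cure_threshold: float = 0.5,
) -> FittedMCM:
    """Fit the penalized mixture cure model by EM.

    Iterates until the maximum absolute parameter change falls below
    ``penalty.em_tolerance`` or ``penalty.em_max_iterations`` is reached.
    The high/low-risk cutoff stored with the fit is the median latency
    linear predictor among training samples predicted susceptible at
    ``cure_threshold``.
    """
    if not (0.0 < cure_threshold < 1.0):
        raise ValueError("cure_threshold must lie in (0, 1)")
    params, w = initialize(data)
    # M-steps are warm-started and only need to improve their objectives;
    # solving them far past the EM tolerance wastes work, so the inner
    # solver tolerance tracks (a tenth of) the EM tolerance.
    solver_cfg = PenaltyConfig(
        lambda_incidence=penalty.lambda_incidence,
        lambda_latency=penalty.lambda_latency,
        standardize=penalty.standardize,
        max_iterations=penalty.max_iterations,
        tolerance=max(penalty.tolerance, 0.1 * penalty.em_tolerance),
        active_set=penalty.active_set,
        em_tolerance=penalty.em_tolerance,
        em_max_iterations=penalty.em_max_iterations,
    )
    X = data.expression
    if penalty.standardize and data.n_genes:
        std = X.std(axis=0)
        std = np.where(std < 1e-12, 1.0, std)
    else:
        std = np.ones(data.n_genes)

    trace = EMTrace()
    b0 = params.incidence_intercept
    b = params.incidence_coefficients
    beta = params.latency_coefficients
    baseline = params.baseline
    prev_ll = -np.inf
    for _ in range(penalty.em_max_iterations):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # per-iteration solver warnings are expected early
            logi = fit_weighted_lasso_logistic(
                X, w, penalty.lambda_incidence, init=b, init_intercept=b0, config=solver_cfg
            )
            b0_new = _cap_intercept(logi.intercept)
            b_new = logi.coefficients
            cox = fit_weighted_lasso_cox(
                X, data.times, data.events, w, penalty.lambda_latency, init=beta, config=solver_cfg
            )
        beta_new = cox.coefficients
        baseline = breslow_baseline(data, w, beta_new)
        change = abs(b0_new - b0)
        if data.n_genes:
            change = max(
                change,
                float(np.max(np.abs(b_new - b))),
                float(np.max(np.abs(beta_new - beta))),
            )
        b0, b, beta = b0_new, b_new, beta_new
        params = MCMParameters(b0, b, beta, baseline)
        ll = penalized_observed_loglik(params, data, penalty, std)
        trace.penalized_loglik.append(ll)
        trace.max_param_change.append(change)
        if ll < prev_ll - _ASCENT_SLACK * max(abs(prev_ll), 1.0):
            warnings.warn(
                f"penalized log-likelihood decreased by {prev_ll - ll:.3e} at "
                f"iteration {trace.n_iterations}",
                EMWarning,
            )
        prev_ll = ll
        if change < penalty.em_tolerance:
            trace.converged = True
            break
        w = e_step(params, data)
    if not trace.converged:
        warnings.warn(
            f"EM did not converge in {penalty.em_max_iterations} iterations "
            f"(last change {trace.max_param_change[-1]:.3e})",
            EMWarning,
        )

    # training risk cutoff: median latency linear predictor among samples
    # predicted susceptible by their posterior weight (events always qualify)
    w_final = e_step(params, data)
    susceptible = w_final >= cure_threshold
    if np.any(susceptible):
        cutoff = float(np.median((X @ beta)[susceptible]))
    else:
        cutoff = float("nan")
        warnings.warn("no training sample predicted susceptible; risk cutoff undefined", EMWarning)
    return FittedMCM(
        parameters=params,
        penalty=penalty,
        trace=trace,
        training_risk_score_cutoff=cutoff,
        cure_threshold=cure_threshold,
        gene_names=np.asarray(data.gene_names, dtype=object),
    )


def default_lambda_grid(
    data: SurvivalDataset,
    n_points: int = 4,
    max_ratio: float = 0.5,
    min_ratio: float = 0.05,
) -> List[Tuple[float, float]]:
    """Geometric grid of (lambda_incidence, lambda_latency) pairs.

    Anchored at the null-model gradients (lambda_max) of each component,
    evaluated at the initialization weights.
    """
    _, w = initialize(data)
    lmax_inc = lambda_max_logistic(data.expression, w)
    lmax_lat = lambda_max_cox(data.expression, data.times, data.events, w)
    ratios = np.geomspace(max_ratio, min_ratio, n_points)
    grid = [
        (float(lmax_inc * ri), float(lmax_lat * rl))
        for ri in ratios
        for rl in ratios
    ]
    return grid


def cross_validate(
    data: SurvivalDataset,
    lambda_grid: Sequence[Tuple[float, float]],
    k_folds: int = 5,
    seed: int = 0,
    penalty_template: Optional[PenaltyConfig] = None,
    cure_threshold: float = 0.5,
) -> Tuple[PenaltyConfig, pd.DataFrame]:
    """Select penalties by k-fold cross-validated held-out log-likelihood.

    Folds are stratified on the event indicator.  For each grid pair the
    model is fitted on k-1 folds and the unpenalized observed-data
    log-likelihood of the held-out fold is recorded; the pair maximizing the
    mean held-out log-likelihood wins, with ties broken toward the larger
    lambda_incidence + lambda_latency (parsimony).
    """
    from sklearn.model_selection import StratifiedKFold

    if k_folds < 2:
        raise ValueError("k_folds must be >= 2")
    if not lambda_grid:
        raise ValueError("lambda grid is empty")
    template = penalty_template or PenaltyConfig()
    skf = StratifiedKFold(n_splits=k_folds, shuffle=True, random_state=seed)
    folds = list(skf.split(np.zeros(data.n_samples), data.events))
    for fi, (tr, _) in enumerate(folds):
        if data.events[tr].sum() < 1:
            raise ValueError(f"training fold {fi} contains no events; reduce k_folds")

    rows = []
    for lam_inc, lam_lat in lambda_grid:
        for fi, (tr, te) in enumerate(folds):
            pen = PenaltyConfig(
                lambda_incidence=lam_inc,
                lambda_latency=lam_lat,
                standardize=template.standardize,
                max_iterations=template.max_iterations,
                tolerance=template.tolerance,
                active_set=template.active_set,
                em_tolerance=template.em_tolerance,
                em_max_iterations=template.em_max_iterations,
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = em_fit(data.subset(tr), pen, cure_threshold=cure_threshold)
            held = observed_loglik(fit.parameters, data.subset(te))
            rows.append(
                {
                    "lambda_incidence": lam_inc,
                    "lambda_latency": lam_lat,
                    "fold": fi,
                    "heldout_loglik": held,
                }
            )
    table = pd.DataFrame(rows)
    means = (
        table.groupby(["lambda_incidence", "lambda_latency"], sort=False)["heldout_loglik"]
        .mean()
        .reset_index()
    )
    means["lambda_sum"] = means["lambda_incidence"] + means["lambda_latency"]
    best = means.sort_values(
        ["heldout_loglik", "lambda_sum"], ascending=[False, False], kind="stable"
    ).iloc[0]
    best_pen = PenaltyConfig(
        lambda_incidence=float(best["lambda_incidence"]),
        lambda_latency=float(best["lambda_latency"]),
        standardize=template.standardize,
        max_iterations=template.max_iterations,
        tolerance=template.tolerance,
        active_set=template.active_set,
        em_tolerance=template.em_tolerance,
        em_max_iterations=template.em_max_iterations,
    )
    return best_pen, table


def selected_genes(fit: FittedMCM) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Nonzero coefficients of the two components, sorted by |coefficient|.

    Returns (cure_gene_table, latency_gene_table): genes with nonzero
    incidence coefficients drive cure versus susceptibility; genes with
    nonzero latency coefficients drive time-to-relapse among susceptibles.
    """

    def table(coef, component):
        nz = np.flatnonzero(coef)
        df = pd.DataFrame(
            {
                "gene": fit.gene_names[nz],
                "coefficient": coef[nz],
                "component": component,
            }
        )
        return df.reindex(df["coefficient"].abs().sort_values(ascending=False, kind="stable").index).reset_index(
            drop=True
        )

    return (
        table(fit.parameters.incidence_coefficients, "incidence"),
        table(fit.parameters.latency_coefficients, "latency"),
    )
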