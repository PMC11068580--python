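"""Cure/risk stratification and Kaplan-Meier machinery.

``predict`` applies a fitted mixture cure model to new expression rows:
susceptibility probability from the incidence component, a cured/susceptible
call at the model's threshold, the latency linear predictor as a risk score,
and a high/low risk split of the predicted susceptibles at the cutoff learnt
on the training set (the trained rule is applied unchanged to new data).

``km_estimate``/``km_by_group`` provide the product-limit curves used to
display the resulting groups, with a log-rank test as a convenience.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import population_survival, susceptibility_probability


@dataclass
class KMCurve:
    """Product-limit estimate with risk-set bookkeeping.

    ``times`` are the distinct observed times; ``survival`` is the
    right-continuous KM estimate at each; ``at_risk`` counts samples at risk
    just before each time; ``n_events`` counts events at each time.
    """

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    n_events: np.ndarray
    group_label: str = ""
    n_samples: int = 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.times,
                "survival": self.survival,
                "at_risk": self.at_risk,
                "n_events": self.n_events,
            }
        )

    def survival_at(self, t):
        """Step-function evaluation (right-continuous; 1 before first time)."""
        idx = np.searchsorted(self.times, np.asarray(t, dtype=float), side="right")
        padded = np.concatenate([[1.0], self.survival])
        return padded[idx]


def km_estimate(times, events, label: str = "") -> KMCurve:
    """Kaplan-Meier product-limit estimator.

    S(t) = prod_{t_k <= t} (1 - d_k / n_k) over distinct observed times,
    with d_k events among n_k at risk.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events).astype(int)
    if times.size == 0:
        raise ValueError("cannot estimate a survival curve from no samples")
    if np.any(times <= 0):
        raise ValueError("times must be strictly positive")
    order = np.argsort(times, kind="stable")
    t = times[order]
    e = events[order]
    uniq, first_idx, counts = np.unique(t, return_index=True, return_counts=True)
    d = np.add.reduceat(e, first_idx)
    n_total = len(t)
    at_risk = n_total - np.concatenate([[0], np.cumsum(counts)[:-1]])
    surv = np.cumprod(1.0 - d / at_risk)
    return KMCurve(
        times=uniq,
        survival=surv,
        at_risk=at_risk,
        n_events=d,
        group_label=label,
        n_samples=n_total,
    )


def km_plateau(times, events) -> float:
    """Final value of the KM curve (the empirical cure-fraction estimate
    when follow-up extends well past the susceptible support)."""
    return float(km_estimate(times, events).survival[-1])


def km_by_group(data, labels, min_group_size: int = 1):
    """One KM curve per label level, in sorted label order.

    ``data`` is a SurvivalDataset (or any object with ``times``/``events``).
    Levels smaller than ``min_group_size`` are still estimated but trigger a
    warning.
    """
    labels = np.asarray(labels, dtype=object)
    if len(labels) != len(data.times):
        raise ValueError("labels must align with samples")
    levels = sorted(set(labels.tolist()))
    if not levels:
        raise ValueError("no groups to stratify by")
    curves = []
    for lev in levels:
        mask = labels == lev
        if mask.sum() < min_group_size:
            warnings.warn(f"group {lev!r} has fewer than {min_group_size} samples", UserWarning)
        curves.append(km_estimate(data.times[mask], data.events[mask], label=str(lev)))
    return curves


def logrank(data, labels) -> float:
    """Log-rank test p-value across label levels (convenience wrapper)."""
    from lifelines.statistics import multivariate_logrank_test

    res = multivariate_logrank_test(data.times, np.asarray(labels, dtype=object), data.events)
    return float(res.p_value)


def predict(fit, expression, horizon: float) -> pd.DataFrame:
    """Per-sample predictions of a fitted mixture cure model.

    Parameters
    ----------
    fit : FittedMCM
        Trained model (carries gene names, cure threshold and the training
        risk-score cutoff).
    expression : pandas.DataFrame
        Samples x genes, indexed by sample id.  Must contain every gene the
        model was trained on (extra columns are ignored); columns are
        reordered to the training order.
    horizon : float
        Time (same unit as training follow-up) at which the population
        survival probability is reported.

    Returns
    -------
    DataFrame indexed by sample id with columns ``susceptibility_probability``,
    ``cure_label`` ({"cured", "susceptible"}), ``risk_score`` (latency linear
    predictor), ``risk_group`` ({"high", "low", "not_applicable"}; scores at
    or below the training cutoff go to "low") and
    ``population_survival_at_horizon``.
    """
    if not isinstance(expression, pd.DataFrame):
        raise TypeError("expression must be a pandas DataFrame indexed by sample id")
    missing = [g for g in fit.gene_names if g not in expression.columns]
    if missing:
        raise ValueError(f"expression is missing {len(missing)} model gene(s): {missing[:10]}")
    X = expression.loc[:, list(fit.gene_names)].to_numpy(dtype=float)
    if not np.all(np.isfinite(X)):
        raise ValueError("expression contains non-finite values")
    params = fit.parameters
    pi = susceptibility_probability(params, X)
    risk = X @ params.latency_coefficients
    cured = pi < fit.cure_threshold
    # boundary ties go to "low" (deterministic, documented)
    risk_group = np.where(cured, "not_applicable", np.where(risk > fit.training_risk_score_cutoff, "high", "low"))
    pop = population_survival(params, X, float(horizon))
    return pd.DataFrame(
        {
            "susceptibility_probability": pi,
            "cure_label": np.where(cured, "cured", "susceptible"),
            "risk_score": risk,
            "risk_group": risk_group,
            "population_survival_at_horizon": np.atleast_1d(pop),
        },
        index=pd.Index(expression.index, name="sample_id"),
    )


def classify_training(fit, data, horizon: float) -> pd.DataFrame:
    """Stratify the *training* cohort by posterior susceptibility.

    For samples whose follow-up entered the fit, the natural susceptibility
    estimate is the E-step posterior, which conditions on the observed
    outcome: every event sample has posterior 1, and a censored sample
    beyond the last event time has posterior 0 (zero-tail).  Classifying the
    training cohort this way makes the predicted-cured group event-free by
    construction — its Kaplan-Meier curve is 1 throughout follow-up —
    which is the behaviour expected of the training display; ``predict``
    (marginal incidence probability) is the rule for samples without
    outcomes.

    Returns the same columns as ``predict``, with
    ``susceptibility_probability`` holding the posterior weight.
    """
    from .model import e_step

    w = e_step(fit.parameters, data)
    risk = data.expression @ fit.parameters.latency_coefficients
    cured = w < fit.cure_threshold
    risk_group = np.where(
        cured, "not_applicable", np.where(risk > fit.training_risk_score_cutoff, "high", "low")
    )
    pop = population_survival(fit.parameters, data.expression, float(horizon))
    return pd.DataFrame(
        {
            "susceptibility_probability": w,
            "cure_label": np.where(cured, "cured", "susceptible"),
            "risk_score": risk,
            "risk_group": risk_group,
            "population_survival_at_horizon": np.atleast_1d(pop),
        },
        index=pd.Index(data.sample_ids, name="sample_id"),
    )
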