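"""Core mixture cure model mathematics.

The model posits a latent susceptible indicator Y_i ~ Bernoulli(pi_i) with
logistic incidence pi_i = expit(b0 + x_i'b), and, conditional on Y_i = 1, a
semi-parametric Cox latency law S_u(t|z) = S0(t)^exp(z'beta) with a
nonparametric (Breslow) baseline.  Population survival is the mixture

    S_pop(t|x, z) = (1 - pi) + pi * S_u(t|z).

``pi`` is the probability of being *susceptible* (uncured).  For
identifiability of the cure fraction the conditional susceptible survival is
forced to zero beyond the last observed event time (zero-tail constraint).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.special import expit


class DataValidationError(ValueError):
    """Raised when a survival dataset violates its invariants."""


@dataclass
class SurvivalDataset:
    """Expression matrix plus per-sample follow-up.

    Parameters
    ----------
    sample_ids : sequence of str
        Unique sample identifiers.
    times : array of float
        Strictly positive follow-up times (one unit throughout, e.g. years).
    events : array of {0, 1}
        1 = relapse/death observed, 0 = censored.
    expression : (n_samples, n_genes) array
        Covariate matrix; values assumed already normalized.
    gene_names : sequence of str
        Unique gene identifiers, one per column.
    group : optional sequence
        External categorical label per sample (e.g. ELN genetic risk).
    """

    sample_ids: np.ndarray
    times: np.ndarray
    events: np.ndarray
    expression: np.ndarray
    gene_names: np.ndarray
    group: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        self.times = np.asarray(self.times, dtype=float)
        self.events = np.asarray(self.events)
        self.expression = np.atleast_2d(np.asarray(self.expression, dtype=float))
        self.gene_names = np.asarray(self.gene_names, dtype=object)
        if self.group is not None:
            self.group = np.asarray(self.group, dtype=object)
        n = len(self.times)
        if self.expression.shape[0] != n or len(self.sample_ids) != n or len(self.events) != n:
            raise DataValidationError("sample_ids, times, events and expression rows must align")
        if self.group is not None and len(self.group) != n:
            raise DataValidationError("group labels must align with samples")
        if np.any(~np.isfinite(self.times)) or np.any(self.times <= 0):
            raise DataValidationError("times must be finite and strictly positive")
        if not np.all(np.isin(self.events, (0, 1))):
            raise DataValidationError("events must be 0 or 1")
        self.events = self.events.astype(int)
        if self.expression.shape[1] != len(self.gene_names):
            raise DataValidationError("gene_names must match expression columns")
        if not np.all(np.isfinite(self.expression)):
            raise DataValidationError("expression matrix contains non-finite values")
        if len(set(self.gene_names)) != len(self.gene_names):
            raise DataValidationError("gene names must be unique")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise DataValidationError("sample ids must be unique")

    @property
    def n_samples(self) -> int:
        return len(self.times)

    @property
    def n_genes(self) -> int:
        return self.expression.shape[1]

    def subset(self, index: Sequence[int]) -> "SurvivalDataset":
        index = np.asarray(index)
        return SurvivalDataset(
            sample_ids=self.sample_ids[index],
            times=self.times[index],
            events=self.events[index],
            expression=self.expression[index],
            gene_names=self.gene_names,
            group=None if self.group is None else self.group[index],
        )


@dataclass
class BaselineHazard:
    """Step-function cumulative baseline hazard at distinct event times.

    ``increments`` are the Breslow jumps of the cumulative hazard; baseline
    survival is S0(t) = exp(-sum of increments at event times <= t).
    """

    event_times: np.ndarray
    increments: np.ndarray
    _cum: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.event_times = np.asarray(self.event_times, dtype=float)
        self.increments = np.asarray(self.increments, dtype=float)
        if self.event_times.size == 0:
            raise DataValidationError("baseline requires at least one event time")
        if np.any(np.diff(self.event_times) <= 0):
            raise DataValidationError("event times must be strictly increasing")
        if np.any(self.increments < 0):
            raise DataValidationError("hazard increments must be non-negative")
        self._cum = np.concatenate([[0.0], np.cumsum(self.increments)])

    @property
    def last_event_time(self) -> float:
        return float(self.event_times[-1])

    def cumulative_hazard(self, t):
        """H0(t) = sum of increments at event times <= t (vectorized)."""
        idx = np.searchsorted(self.event_times, np.asarray(t, dtype=float), side="right")
        return self._cum[idx]

    def hazard_increment(self, t):
        """Discrete hazard carried forward: increment at the latest knot <= t.

        At an in-sample event time this is the increment at that time; between
        knots (held-out times) the most recent increment is used; before the
        first event time it is zero.
        """
        t = np.asarray(t, dtype=float)
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        out = np.where(idx >= 0, self.increments[np.clip(idx, 0, None)], 0.0)
        return out

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"event_time": self.event_times, "cumulative_hazard": self._cum[1:]}
        )


@dataclass
class MCMParameters:
    """Full parameter set: incidence (logistic), latency (Cox), baseline."""

    incidence_intercept: float
    incidence_coefficients: np.ndarray
    latency_coefficients: np.ndarray
    baseline: BaselineHazard

    def __post_init__(self) -> None:
        self.incidence_coefficients = np.asarray(self.incidence_coefficients, dtype=float)
        self.latency_coefficients = np.asarray(self.latency_coefficients, dtype=float)
        if not np.isfinite(self.incidence_intercept):
            raise DataValidationError("incidence intercept must be finite")
        if not (np.all(np.isfinite(self.incidence_coefficients)) and np.all(np.isfinite(self.latency_coefficients))):
            raise DataValidationError("coefficients must be finite")


def susceptibility_probability(params: MCMParameters, x) -> np.ndarray:
    """pi(x) = expit(b0 + x'b), the probability of being susceptible."""
    x = np.asarray(x, dtype=float)
    eta = params.incidence_intercept + x @ params.incidence_coefficients
    return expit(eta)


def susceptible_survival(params: MCMParameters, z, t):
    """Conditional survival of susceptibles, S_u(t|z) = S0(t)^exp(z'beta).

    Applies the zero-tail constraint: exactly 0 for t beyond the last event
    time.  ``z`` may be a single expression row or a matrix of rows; ``t`` a
    scalar or an array broadcastable against the rows.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be non-negative")
    z = np.asarray(z, dtype=float)
    eta = z @ params.latency_coefficients
    H = params.baseline.cumulative_hazard(t)
    s = np.exp(-H * np.exp(eta))
    s = np.where(t > params.baseline.last_event_time, 0.0, s)
    if s.ndim == 0:
        return float(s)
    return s


def population_survival(params: MCMParameters, x, t):
    """Marginal survival S_pop = (1 - pi) + pi * S_u; plateaus at 1 - pi."""
    pi = susceptibility_probability(params, x)
    su = susceptible_survival(params, x, t)
    out = (1.0 - pi) + pi * su
    if np.ndim(out) == 0:
        return float(out)
    return np.asarray(out)


def e_step(params: MCMParameters, data: SurvivalDataset) -> np.ndarray:
    """Posterior probability of susceptibility given the observed data.

    Events are susceptible with certainty (w = 1).  Censored samples get

        w_i = pi_i S_u(t_i|z_i) / (1 - pi_i + pi_i S_u(t_i|z_i)),

    which is 0 beyond the last event time (zero-tail).  The denominator can
    vanish only when pi_i = 1 and S_u = 0; that corner is defined as w = 0.
    """
    pi = susceptibility_probability(params, data.expression)
    su = susceptible_survival(params, data.expression, data.times)
    num = pi * su
    den = (1.0 - pi) + num
    with np.errstate(invalid="ignore", divide="ignore"):
        w = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
    w = np.clip(w, 0.0, 1.0)
    w[data.events == 1] = 1.0
    return w


def breslow_baseline(
    data: SurvivalDataset, weights: np.ndarray, latency_coefficients: np.ndarray
) -> BaselineHazard:
    """Weighted Breslow estimator of the baseline cumulative hazard.

    Increment at distinct event time t_k is d_k / sum_{j: t_j >= t_k}
    w_j exp(z_j'beta), with d_k the number of events at t_k (Breslow tie
    handling: one shared denominator per tied time).
    """
    if data.events.sum() < 1:
        raise ValueError("Breslow baseline requires at least one event")
    weights = np.asarray(weights, dtype=float)
    eta = data.expression @ np.asarray(latency_coefficients, dtype=float)
    we = weights * np.exp(eta)
    order = np.argsort(data.times, kind="stable")
    t_sorted = data.times[order]
    e_sorted = data.events[order]
    we_sorted = we[order]
    # suffix sums give the risk-set mass at each sorted position
    suffix = np.cumsum(we_sorted[::-1])[::-1]
    uniq, first_idx = np.unique(t_sorted, return_index=True)
    d = np.add.reduceat(e_sorted, first_idx)
    has_event = d > 0
    event_times = uniq[has_event]
    denom = suffix[first_idx][has_event]
    bad = denom <= 0
    if np.any(bad):
        raise FloatingPointError(
            f"zero risk-set mass at event time(s) {event_times[bad].tolist()}"
        )
    increments = d[has_event] / denom
    return BaselineHazard(event_times=event_times, increments=increments)


def observed_loglik(params: MCMParameters, data: SurvivalDataset, eps: float = 1e-12) -> float:
    """Observed-data log-likelihood of the mixture cure model.

    Events contribute log[pi h_u(t) S_u(t)] with h_u the discrete baseline
    hazard times exp(z'beta); censored samples contribute
    log[1 - pi + pi S_u(t)].  Probabilities are floored at ``eps`` before
    taking logs so the value is always finite.
    """
    X = data.expression
    pi = susceptibility_probability(params, X)
    eta = X @ params.latency_coefficients
    H = params.baseline.cumulative_hazard(data.times)
    reta = np.exp(eta)
    su = np.exp(-H * reta)
    su = np.where(data.times > params.baseline.last_event_time, 0.0, su)
    h0 = params.baseline.hazard_increment(data.times)

    ev = data.events == 1
    ll = 0.0
    if np.any(ev):
        ll += np.sum(
            np.log(np.maximum(pi[ev], eps))
            + np.log(np.maximum(h0[ev], eps))
            + eta[ev]
            - H[ev] * reta[ev]
        )
    cen = ~ev
    if np.any(cen):
        ll += np.sum(np.log(np.maximum((1.0 - pi[cen]) + pi[cen] * su[cen], eps)))
    return float(ll)
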