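"""Discrimination metrics: Harrell's C and time-dependent AUC at a horizon.

Both metrics are rank-based and therefore invariant to strictly monotone
transformations of the marker.  The time-dependent AUC is the
cumulative-case / dynamic-control estimator with inverse-probability-of-
censoring weights (Kaplan-Meier estimate of the censoring survival), so it
reduces exactly to the Mann-Whitney AUC of the binary horizon outcome when
no censoring occurs before the horizon.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import population_survival, susceptibility_probability
from .stratify import km_estimate


@dataclass
class EvaluationReport:
    c_statistic: float
    auc_at_horizon: float
    horizon: float
    n_comparable_pairs: int
    marker_definition: str


def c_statistic(risk, times, events) -> float:
    """Harrell's concordance over comparable pairs.

    A pair (i, j) is comparable iff i had an event and either t_i < t_j or
    t_i == t_j with j censored.  Concordant pairs have risk_i > risk_j;
    risk ties count 1/2.
    """
    risk = np.asarray(risk, dtype=float)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events).astype(int)
    t_i = times[:, None]
    t_j = times[None, :]
    comparable = (events[:, None] == 1) & (
        (t_i < t_j) | ((t_i == t_j) & (events[None, :] == 0))
    )
    np.fill_diagonal(comparable, False)
    n_pairs = int(comparable.sum())
    if n_pairs == 0:
        raise ValueError("no comparable pairs; concordance is undefined")
    r_i = risk[:, None]
    r_j = risk[None, :]
    concordant = (r_i > r_j) & comparable
    tied = (r_i == r_j) & comparable
    return float((concordant.sum() + 0.5 * tied.sum()) / n_pairs)


def n_comparable_pairs(times, events) -> int:
    times = np.asarray(times, dtype=float)
    events = np.asarray(events).astype(int)
    comp = (events[:, None] == 1) & (
        (times[:, None] < times[None, :])
        | ((times[:, None] == times[None, :]) & (events[None, :] == 0))
    )
    np.fill_diagonal(comp, False)
    return int(comp.sum())


def _censoring_survival_before(times, events, at):
    """G(t-): KM estimate of the censoring survival just before each ``at``."""
    km = km_estimate(times, 1 - np.asarray(events).astype(int))
    idx = np.searchsorted(km.times, np.asarray(at, dtype=float), side="left")
    padded = np.concatenate([[1.0], km.survival])
    return padded[idx]


def auc_at_time(marker, times, events, horizon: float) -> float:
    """IPCW cumulative/dynamic AUC at ``horizon``.

    Cases are samples with an event at or before the horizon, weighted by
    1/G(t_i-) where G is the KM censoring survival; controls are samples
    still under observation beyond the horizon.  Marker ties count 1/2.
    """
    marker = np.asarray(marker, dtype=float)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events).astype(int)
    cases = (times <= horizon) & (events == 1)
    controls = times > horizon
    if not np.any(cases) or not np.any(controls):
        raise ValueError("AUC undefined: need at least one case and one control at the horizon")
    G = _censoring_survival_before(times, events, times[cases])
    if np.any(G <= 0):
        raise ValueError("censoring survival vanished before a case time; AUC undefined")
    w = 1.0 / G
    m_cases = marker[cases]
    m_ctrl = np.sort(marker[controls])
    n_ctrl = m_ctrl.size
    below = np.searchsorted(m_ctrl, m_cases, side="left")
    ties = np.searchsorted(m_ctrl, m_cases, side="right") - below
    num = float(np.sum(w * (below + 0.5 * ties)))
    den = float(np.sum(w) * n_ctrl)
    return num / den


def evaluate_model(fit, data, horizon: float, marker: str = "population_risk") -> EvaluationReport:
    """Score a fitted mixture cure model on a survival dataset.

    ``marker`` selects the risk ordering fed to both metrics:

    * ``"population_risk"`` (default): 1 - S_pop(horizon | x), the model's
      probability of relapse by the horizon — the only choice that combines
      the incidence and latency components;
    * ``"risk_score"``: the latency linear predictor z'beta;
    * ``"susceptibility"``: the incidence probability pi(x).
    """
    X = data.expression
    params = fit.parameters
    if marker == "population_risk":
        values = 1.0 - np.asarray(population_survival(params, X, float(horizon)))
        definition = "1 - population survival at horizon"
    elif marker == "risk_score":
        values = X @ params.latency_coefficients
        definition = "latency linear predictor"
    elif marker == "susceptibility":
        values = susceptibility_probability(params, X)
        definition = "susceptibility probability"
    else:
        raise ValueError(f"unknown marker {marker!r}")
    return EvaluationReport(
        c_statistic=c_statistic(values, data.times, data.events),
        auc_at_horizon=auc_at_time(values, data.times, data.events, horizon),
        horizon=float(horizon),
        n_comparable_pairs=n_comparable_pairs(data.times, data.events),
        marker_definition=definition,
    )
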