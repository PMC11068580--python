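"""Shared fixtures: random survival instances and the pilot benchmark fit."""

from __future__ import annotations

import warnings

import numpy as np
import pytest

import curemix as cm


def random_survival(rng, n, censor_frac=0.3, tie_free=True):
    """Small random right-censored sample (times, events) for oracle tests."""
    times = rng.exponential(2.0, size=n) + 0.05
    if not tie_free:
        times = np.round(times, 1) + 0.1
    events = (rng.uniform(size=n) > censor_frac).astype(int)
    if events.sum() == 0:
        events[rng.integers(n)] = 1
    return times, events


@pytest.fixture(scope="session")
def pilot():
    """The benchmark cohort and its cross-validated fit, computed once.

    n = 400 patients, 200 genes (40 correlated blocks), five true genes per
    component with |effect| 1.0, cure fraction ~0.4; 5-fold CV over a 4x4
    penalty grid, then a full EM fit at the selected penalties.
    """
    cfg = cm.pilot_config(seed=7)
    data, truth = cm.simulate_cohort(cfg)
    grid = cm.default_lambda_grid(data, n_points=4, max_ratio=0.5, min_ratio=0.05)
    template = cm.PenaltyConfig(em_max_iterations=15)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        best, cv_table = cm.cross_validate(
            data, grid, k_folds=5, seed=7, penalty_template=template
        )
        fit = cm.em_fit(
            data,
            cm.PenaltyConfig(
                lambda_incidence=best.lambda_incidence,
                lambda_latency=best.lambda_latency,
            ),
        )
    return {
        "config": cfg,
        "data": data,
        "truth": truth,
        "grid": grid,
        "best": best,
        "cv_table": cv_table,
        "fit": fit,
    }


@pytest.fixture()
def small_cohort():
    """A quick 120 x 30 cohort with modest signal, for unit tests."""
    cfg = cm.GeneratorConfig(
        n_samples=120,
        n_genes=30,
        n_blocks=10,
        n_true_incidence=3,
        n_true_latency=3,
        seed=1,
    )
    return cm.simulate_cohort(cfg)
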