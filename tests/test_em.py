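"""EM driver: initialization, ascent, degenerate reductions, CV, gene lists."""

import warnings

import numpy as np
import pytest
from scipy.special import expit

import curemix as cm
from curemix.em import EMWarning, initialize
from curemix.model import SurvivalDataset


def make_dataset(times, events, X=None, p=0):
    times = np.asarray(times, float)
    n = len(times)
    X = np.zeros((n, p)) if X is None else np.asarray(X, float)
    return SurvivalDataset(
        sample_ids=np.array([f"s{i}" for i in range(n)], dtype=object),
        times=times,
        events=np.asarray(events),
        expression=X,
        gene_names=np.array([f"g{j}" for j in range(X.shape[1])], dtype=object),
    )


class TestInitialize:
    def test_all_events_give_unit_weights(self):
        data = make_dataset([1.0, 2.0, 3.0], [1, 1, 1], p=2)
        params, w = initialize(data)
        np.testing.assert_array_equal(w, 1.0)
        assert np.all(params.incidence_coefficients == 0)
        assert np.all(params.latency_coefficients == 0)

    def test_censored_weight_reaches_zero_at_plateau(self):
        # last sample censored at the plateau has weight 0
        data = make_dataset([1.0, 2.0, 5.0], [1, 1, 0], p=0)
        _, w = initialize(data)
        assert w[2] == 0.0
        assert w[0] == w[1] == 1.0

    def test_initial_penalized_loglik_finite(self, small_cohort):
        data, _ = small_cohort
        params, w = initialize(data)
        ll = cm.penalized_observed_loglik(params, data, cm.PenaltyConfig())
        assert np.isfinite(ll)

    def test_no_events_unfittable(self):
        data = make_dataset([1.0, 2.0], [0, 0], p=1)
        with pytest.raises(ValueError, match="no events"):
            initialize(data)


class TestEMFit:
    def test_zero_censoring_degenerates_to_all_susceptible(self):
        rng = np.random.default_rng(0)
        data = make_dataset(
            rng.exponential(1, 40) + 0.01, np.ones(40, dtype=int), X=rng.standard_normal((40, 3))
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = cm.em_fit(data, cm.PenaltyConfig(lambda_incidence=5.0, lambda_latency=5.0))
        # fractional response all ones: intercept runs to the cap, pi -> 1
        assert fit.parameters.incidence_intercept == pytest.approx(15.0)
        pi = cm.susceptibility_probability(fit.parameters, data.expression)
        assert np.all(pi > 0.999)

    def test_full_shrinkage_gives_intercept_only_model(self, small_cohort):
        data, _ = small_cohort
        _, w0 = initialize(data)
        lmax_i = cm.lambda_max_logistic(data.expression, w0)
        lmax_l = cm.lambda_max_cox(data.expression, data.times, data.events, w0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = cm.em_fit(
                data,
                cm.PenaltyConfig(lambda_incidence=3 * lmax_i, lambda_latency=3 * lmax_l),
            )
        assert np.all(fit.parameters.incidence_coefficients == 0)
        assert np.all(fit.parameters.latency_coefficients == 0)
        pi = cm.susceptibility_probability(fit.parameters, data.expression)
        assert np.ptp(pi) == pytest.approx(0.0, abs=1e-12)

    def test_ascent_on_small_random_cohorts(self):
        for seed in range(3):
            cfg = cm.GeneratorConfig(
                n_samples=60, n_genes=10, n_blocks=5, n_true_incidence=2, n_true_latency=2, seed=seed
            )
            data, _ = cm.simulate_cohort(cfg)
            _, w0 = initialize(data)
            lam_i = 0.3 * cm.lambda_max_logistic(data.expression, w0)
            lam_l = 0.3 * cm.lambda_max_cox(data.expression, data.times, data.events, w0)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = cm.em_fit(data, cm.PenaltyConfig(lambda_incidence=lam_i, lambda_latency=lam_l))
            assert fit.trace.monotone(1e-8), f"likelihood decreased for seed {seed}"

    def test_nonparametric_cure_reduction_without_covariates(self):
        # with p = 0 the fit collapses to the nonparametric cure model:
        # 1 - expit(intercept) ~ the KM plateau under long follow-up
        cfg = cm.GeneratorConfig(
            n_samples=500,
            n_genes=1,
            n_blocks=1,
            n_true_incidence=0,
            n_true_latency=0,
            incidence_intercept=0.4,
            susceptible_time_cap=4.0,
            censoring_max=12.0,
            seed=21,
        )
        data, _ = cm.simulate_cohort(cfg)
        data0 = make_dataset(data.times, data.events, p=0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = cm.em_fit(data0, cm.PenaltyConfig())
        plateau = cm.km_plateau(data.times, data.events)
        fitted_cure = 1.0 - expit(fit.parameters.incidence_intercept)
        assert abs(fitted_cure - plateau) < 2 * np.sqrt(plateau * (1 - plateau) / 500)

    def test_permutation_invariance(self, small_cohort):
        data, _ = small_cohort
        perm = np.random.default_rng(5).permutation(data.n_samples)
        shuffled = data.subset(perm)
        pen = cm.PenaltyConfig(lambda_incidence=4.0, lambda_latency=4.0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            f1 = cm.em_fit(data, pen)
            f2 = cm.em_fit(shuffled, pen)
        np.testing.assert_allclose(
            f1.parameters.incidence_coefficients, f2.parameters.incidence_coefficients, atol=1e-6
        )
        np.testing.assert_allclose(
            f1.parameters.latency_coefficients, f2.parameters.latency_coefficients, atol=1e-6
        )
        assert f1.training_risk_score_cutoff == pytest.approx(f2.training_risk_score_cutoff, abs=1e-6)


class TestCrossValidate:
    def test_single_point_grid_returned(self, small_cohort):
        data, _ = small_cohort
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            best, table = cm.cross_validate(
                data, [(5.0, 6.0)], k_folds=3, seed=0,
                penalty_template=cm.PenaltyConfig(em_max_iterations=5),
            )
        assert (best.lambda_incidence, best.lambda_latency) == (5.0, 6.0)
        assert len(table) == 3

    def test_seeded_determinism(self, small_cohort):
        data, _ = small_cohort
        grid = [(8.0, 8.0), (4.0, 4.0)]
        kw = dict(k_folds=3, penalty_template=cm.PenaltyConfig(em_max_iterations=5))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            b1, t1 = cm.cross_validate(data, grid, seed=3, **kw)
            b2, t2 = cm.cross_validate(data, grid, seed=3, **kw)
        assert t1.equals(t2)
        assert (b1.lambda_incidence, b1.lambda_latency) == (b2.lambda_incidence, b2.lambda_latency)

    def test_tie_breaks_toward_stronger_shrinkage(self, small_cohort):
        data, _ = small_cohort
        # duplicate grid point: identical mean loglik, larger sum must win
        grid = [(4.0, 4.0), (4.0, 4.0)]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            best, _ = cm.cross_validate(
                data, grid, k_folds=3, seed=0,
                penalty_template=cm.PenaltyConfig(em_max_iterations=3),
            )
        assert (best.lambda_incidence, best.lambda_latency) == (4.0, 4.0)

    def test_outcome_permutation_empties_the_support(self):
        # decoupling outcomes from expression should drive CV to heavy shrinkage
        cfg = cm.GeneratorConfig(
            n_samples=150, n_genes=30, n_blocks=10, n_true_incidence=3, n_true_latency=3,
            effect_size_incidence=1.5, effect_size_latency=1.5, seed=30,
        )
        data, _ = cm.simulate_cohort(cfg)
        sizes = []
        for pseed in range(3):
            perm = np.random.default_rng(pseed).permutation(data.n_samples)
            permuted = SurvivalDataset(
                sample_ids=data.sample_ids,
                times=data.times[perm],
                events=data.events[perm],
                expression=data.expression,
                gene_names=data.gene_names,
            )
            grid = cm.default_lambda_grid(permuted, n_points=3, max_ratio=0.9, min_ratio=0.1)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                best, _ = cm.cross_validate(
                    permuted, grid, k_folds=3, seed=pseed,
                    penalty_template=cm.PenaltyConfig(em_max_iterations=8),
                )
                fit = cm.em_fit(
                    permuted,
                    cm.PenaltyConfig(
                        lambda_incidence=best.lambda_incidence,
                        lambda_latency=best.lambda_latency,
                        em_max_iterations=20,
                    ),
                )
            sizes.append(
                (fit.parameters.incidence_coefficients != 0).sum()
                + (fit.parameters.latency_coefficients != 0).sum()
            )
        assert np.median(sizes) <= 4  # near-empty supports under the null


class TestSelectedGenes:
    def test_support_extraction_and_sorting(self, small_cohort):
        data, _ = small_cohort
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = cm.em_fit(data, cm.PenaltyConfig(lambda_incidence=3.0, lambda_latency=3.0))
        cure_tab, lat_tab = cm.selected_genes(fit)
        assert len(cure_tab) == (fit.parameters.incidence_coefficients != 0).sum()
        assert len(lat_tab) == (fit.parameters.latency_coefficients != 0).sum()
        assert (cure_tab["component"] == "incidence").all()
        for tab in (cure_tab, lat_tab):
            mags = tab["coefficient"].abs().to_numpy()
            assert np.all(np.diff(mags) <= 1e-15)

    def test_fully_shrunk_fit_gives_empty_tables(self, small_cohort):
        data, _ = small_cohort
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = cm.em_fit(data, cm.PenaltyConfig(lambda_incidence=1e4, lambda_latency=1e4))
        cure_tab, lat_tab = cm.selected_genes(fit)
        assert cure_tab.empty and lat_tab.empty
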