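# Methods

## Model

Let T be the time to relapse or death and x a vector of (already
normalized) gene-expression covariates. A latent indicator Y distinguishes
susceptible (Y = 1) from cured (Y = 0) patients; cured patients never
experience the event. The population survival function is the mixture

    S_pop(t | x) = (1 - pi(x)) + pi(x) * S_u(t | x)

with

* **incidence** — pi(x) = expit(b0 + x'b): a logistic model for the
  probability of being susceptible. Throughout the package pi denotes the
  probability of *susceptibility*; the genes with nonzero b are the "cure
  genes" (they move patients between the cured and susceptible classes, in
  either direction depending on sign).
* **latency** — S_u(t | x) = S0(t)^exp(x'beta): a proportional-hazards
  model for event timing among susceptibles, with nonparametric baseline
  S0(t) = exp(-H0(t)), H0 a step function with jumps at observed event
  times.
* **zero-tail constraint** — S_u(t | x) := 0 for t beyond the last
  observed event time. Without it the cure fraction is not identified
  against heavy censoring: a patient censored very late could always be
  explained as "susceptible but lucky". With it, late-censored patients are
  classified cured with certainty, which is what makes the KM plateau
  interpretable as a cure fraction.

Both coefficient vectors carry L1 penalties (lambda_incidence on b,
lambda_latency on beta; intercept unpenalized), giving sparse, directly
reportable gene lists. The penalties are independent because the two
components have no reason to share a sparsity level.

## Estimation

The observed-data log-likelihood is

    sum_i  delta_i [log pi_i + log h_u(t_i|x_i) + log S_u(t_i|x_i)]
         + (1 - delta_i) log[1 - pi_i + pi_i S_u(t_i|x_i)]

with h_u the discrete hazard implied by the Breslow baseline. It is
maximized (minus the penalties) by EM over Y:

1. **E-step.** w_i = delta_i + (1 - delta_i) * pi_i S_u(t_i) /
   (1 - pi_i + pi_i S_u(t_i)). Events are susceptible with certainty;
   censored patients beyond the last event time get w = 0 (zero-tail). The
   degenerate corner pi = 1, S_u = 0 is defined as w = 0.
2. **Incidence M-step.** Fractional-response logistic LASSO with response
   w: IRLS with coordinate-wise soft-thresholding (the classic
   penalized-GLM scheme), working weights floored at 1e-5 to avoid
   divergence at fitted probabilities near 0/1, step-halving so the
   penalized objective never decreases, and an explicit stationarity (KKT)
   check before convergence is declared.
3. **Latency M-step.** Case-weighted Cox partial likelihood
   sum_i delta_i [x_i'beta - log sum_{t_j >= t_i} w_j e^{x_j'beta}] minus
   the penalty, with Breslow tie handling. Events carry weight 1; censored
   patients enter only through the weighted risk sets. Solved by
   proximal Newton with a diagonal Hessian approximation and the same CD
   kernel, step-halving and KKT check.
4. **Baseline refresh.** Weighted Breslow estimator: the jump at distinct
   event time t_k is d_k / sum_{t_j >= t_k} w_j exp(x_j'beta). Given the
   weights, (beta, H0) obtained this way jointly maximize the latency part
   of the expected complete-data log-likelihood, so the EM ascent argument
   goes through.

Because every M-step is warm-started from the previous parameters and can
only improve its objective, the penalized observed-data log-likelihood is
non-decreasing up to floating-point slack (generalized EM). The trace
monitors this each iteration (relative slack 1e-8) and warns rather than
assumes.

Initialization: coefficients at zero; censored weights from the
Kaplan-Meier curve as w_i = 1 - plateau / S_KM(t_i) — the KM estimate of
P(susceptible | T > t_i) when the final KM value is read as the cure
fraction; baseline from the weighted Breslow at beta = 0.

### Numerical choices

* Column standardization inside both solvers (penalty applied on the
  standardized scale, coefficients reported on the original scale) —
  LASSO is scale-sensitive.
* Probability flooring at 1e-12 inside logs; likelihood always finite.
* Incidence intercept capped at |15|: with no censoring the fractional
  response is identically 1 and the intercept diverges; the cap keeps the
  degenerate all-susceptible fit finite.
* The discrete hazard at an off-knot time (held-out data in CV) is carried
  forward from the latest knot at or before it; in-sample event times are
  knots, so in-sample likelihoods are unaffected.
* Ties: Breslow convention everywhere (one shared risk-set denominator per
  tied event time), consistent with the Breslow baseline under weighting.
* Risk-group boundary: a risk score exactly at the cutoff goes to "low".
* Solver controls: `PenaltyConfig.tolerance` (default 1e-8, max absolute
  coefficient change) and `max_iterations` (200) govern the coordinate
  descent; `em_tolerance` (1e-4) and `em_max_iterations` (100) govern the
  EM loop. Inside EM the solver tolerance is relaxed to a tenth of the EM
  tolerance: M-steps are warm-started and only need improvement, and exact
  inner solves cost several-fold runtime for no statistical gain. The CD
  kernels are numba-compiled.

### Penalty selection

k-fold cross-validation (default k = 5), folds stratified on the event
indicator, criterion = mean held-out *unpenalized* observed-data
log-likelihood — the quantity the EM maximizes, so tuning and fitting agree
(a C-statistic criterion is a reasonable alternative; it optimizes ranking
rather than fit). Ties break toward the larger lambda sum (parsimony). The
default grid is geometric per component between 0.5 and 0.05 times that
component's lambda_max (the null-model gradient bound computed at the
initialization weights); CV refits are capped at 15 EM iterations, which is
enough to rank penalty pairs.

## Classification and stratification

Two rules, for two situations:

* **New samples** (`predict`): marginal susceptibility pi(x) from the
  incidence component, thresholded at `cure_threshold` (default 0.5, the
  symmetric Bayes rule absent a stated cost ratio). This is the deployable
  rule — it uses expression only.
* **The fitted cohort** (`classify_training`): the E-step posterior w,
  which additionally conditions on each patient's observed follow-up.
  Events have w = 1 and are always called susceptible; censored patients
  past the last event time have w = 0 and are always called cured. The
  predicted-cured group is therefore event-free by construction and its KM
  curve rides at 1 — the expected training-set display for a cure model.

The high/low risk cutoff is the median latency linear predictor x'beta
among training samples predicted susceptible (posterior rule); it is stored
in the fitted model and applied unchanged to new data, so test-set strata
are defined by the trained rule. Arbitrary external subgroup labels (e.g.
ELN genetic-risk classes) can be passed to `km_by_group`; the package never
computes such classifications itself.

## Evaluation

* **Harrell's C**: fraction of comparable pairs ordered correctly by the
  marker; pair (i, j) comparable iff i had an event and t_i < t_j (or
  t_i = t_j with j censored); marker ties count 1/2.
* **Time-dependent AUC at a horizon**: cumulative-case / dynamic-control
  estimator with inverse-probability-of-censoring weights from the KM
  estimate of the censoring distribution (cases weighted by 1/G(t_i-)).
  With no censoring before the horizon it reduces exactly to the
  Mann-Whitney AUC of the binary outcome 1[T <= horizon].
* Default marker: 1 - S_pop(horizon | x), the model's own probability of
  relapse by the horizon — the only marker combining both components. The
  latency score x'beta and the incidence probability pi(x) are exposed as
  alternatives. Both metrics are rank-based, hence invariant to monotone
  marker transformations.

## Synthetic cohorts

The generator draws standardized expression in equicorrelated blocks
(common latent factor per block; singleton blocks reduce exactly to
independent noise), sparse true effects with random signs in each
component, susceptibility from the logistic incidence law, event times for
susceptibles from a Weibull proportional-hazards law *truncated* (by
inverse-CDF conditioning, not censoring) at `susceptible_time_cap`, and
uniform administrative censoring on (0, `censoring_max`). Truncation
rather than censoring makes the KM plateau a genuine cure phenomenon and
satisfies the zero-tail assumption by construction. Cured patients have
T = +infinity and are always censored.

Defaults emulate the motivating cohort scale: 306 patients, 2000 genes in
200 blocks (within-block correlation 0.3 — typical of co-expression
modules), time in years, Weibull shape 1.2 / scale 1.5 y (median relapse
within ~1.5 y), susceptible support (0, 8] y, censoring horizon 10 y,
incidence intercept 0.5 (cure fraction ≈ 0.4, matching the long plateau of
such cohorts). The generator warns when the censoring horizon is shorter
than the susceptible support, because then the plateau is not revealed.

What it does **not** emulate: raw counts, library-size or batch effects,
non-normal expression marginals, covariate-dependent censoring, competing
risks. Passing tests on generated data therefore demonstrate correctness
of the estimator under its own assumptions, not robustness to the ways
real RNA-seq data violate them.

### Benchmark ("pilot") conditions

`pilot_config`: n = 400, p = 200 genes in 40 blocks, five true genes per
component with |effect| = 1.0, incidence intercept 0.4 (realized cure
fraction ≈ 0.43), seed 7; penalties by 5-fold CV over the default 4x4
grid. These sizes keep a full cross-validated analysis in the low minutes
on one core while leaving the problem genuinely high-dimensional relative
to the signal (10 true coefficients among 400). On this benchmark the
fitted supports contain all true genes of both components with correct
signs; the achieved sensitivity (1.0/1.0) is frozen in the test suite as a
regression bound.

## Design choices that were genuinely open

* **Sign convention**: pi is P(susceptible). The alternative (modeling
  P(cured)) only flips coefficient signs; this direction makes the E-step
  and the logistic response direct.
* **Independent penalties** per component rather than a shared one: the
  two gene lists have no reason to be equally sparse.
* **CV criterion**: held-out log-likelihood rather than C — see above.
* **Posterior versus marginal classification of the fitted cohort**: the
  posterior rule is used for training-set displays (see Classification);
  the marginal rule for anything without outcomes.
* **Median risk-score cutoff**: produces comparably sized risk groups and
  assumes nothing about the risk distribution; any quantile could be used.

## Known limitations

* No time-varying covariates, competing risks, or parametric latency
  variants; elastic-net/MCP/SCAD penalties are out of scope.
* The zero-tail constraint makes the cure call for late-censored patients
  deterministic; with short follow-up the cure fraction is inflated (the
  generator warns in the analogous situation).
* Standard LASSO caveats apply to the gene lists: correlated genes within
  a block share credit, and selected sets are sparse summaries, not
  complete sets of associated genes.
* The diagonal-Hessian proximal-Newton Cox solver converges linearly; for
  p far beyond a few thousand a specialized path algorithm would be
  preferable.
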