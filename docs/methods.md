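# Methods

## Estimand and estimator

The estimand is the average treatment effect on the risk-difference scale,
ψ = E[Y¹ − Y⁰], for a binary treatment A and binary outcome Y given a
covariate vector L sufficient for confounding control. The estimator is a
targeted maximum likelihood estimator (TMLE): initial estimates of the two
nuisance functions — the propensity score g(L) = P(A=1|L) and the outcome
regression q_a(L) = P(Y=1|A=a,L) — are updated by a one-parameter logistic
fluctuation

    logit q*(A,L) = logit q(A,L) + ε·H(A,L),    H = A/g − (1−A)/(1−g),

with ε fit by maximum likelihood using logit q as an offset (a single shared ε
for both arms; the two-ε variant is an equally defensible convention and was
not adopted). The point estimate is the plug-in mean of q₁* − q₀* and the
variance comes from the sample variance of the estimated efficient influence
curve, IC = H(Y − q*_A) + (q₁* − q₀*) − ψ̂. After the update the empirical mean
of H(Y − q*_A) is zero up to solver tolerance; this score identity is asserted
in the tests because it is the defining property of the targeting step.

## Double cross-fitting

Flexible machine-learning nuisance estimators can break the empirical-process
(Donsker) conditions behind the usual TMLE variance theory. Double
cross-fitting (DCF) restores valid inference by using three pairwise-disjoint
index sets per estimate: one to train g, one to train q, and one on which the
targeted contrast is evaluated. One *repetition* partitions the n records into
p non-overlapping splits of near-equal size (sizes differ by at most one) and
produces p split estimates, one per estimation split s, which are averaged:

    ATE_r = (1/p) Σ_s ATE_s,        var_r = (1/p) Σ_s Var̂(IC_s)/n.

The per-split variance is scaled by the **full** sample size n, not the
estimation-split size n/p: the p split estimates are computed on disjoint
records and are averaged, so Var(ATE_r) ≈ (1/p²)Σ_s Var(IC_s)/(n/p)
= mean_s Var̂(IC_s)/n. Scaling by n/p instead would overstate the variance of
the average by a factor of ~p.

Because a single partition is noisy, the whole process is repeated r times
with fresh random partitions. The overall estimate is the **median** of the
repetition estimates, and the overall variance is the median of the
within-plus-between terms:

    ψ̂ = median_r(ATE_r),    var = median_r( var_r + (ATE_r − ψ̂)² ),

with the 95% CI ψ̂ ± 1.96·√var. Medians make the aggregation robust to the
occasional failed repetition, which is recorded and excluded rather than
retried (an opt-in retry-with-fresh-seed mode exists). With an even number of
successful repetitions the median is the mean of the two central order
statistics.

### Role assignment schemes

* **Generalization 1 (equal splits).** Each role uses exactly one split,
  assigned cyclically: estimation split s trains g on split s−1 and q on
  split s−2 (labels mod p). The opposite orientation (g from s−2, q from s−1)
  is statistically exchangeable; one orientation is fixed and documented here.
  For p > 3, the remaining p−3 splits are unused within any single triple
  (each split still serves each role exactly once per repetition).
* **Generalization 2 (full data use).** Estimation split s is held out and
  the remaining p−1 splits are divided alternately, in cyclic order s−1, s−2,
  …, between the propensity pool (odd positions) and the outcome pool (even
  positions). Every record is used in every triple, and the two training
  pools have (p−1)/2 splits each, which requires odd p. The alternation
  direction is a free convention; the backward direction is fixed here because
  it makes the two schemes coincide *exactly* (bitwise, under shared seeds) at
  p = 3, which is also the natural comparison anchor between them. For even p
  an opt-in mode (`pool_even_splits=True`) pools the p−1 remaining splits'
  records and re-splits them into two equal halves.

Discordance — pairwise disjointness of the three index sets of every role
triple — is validated on every plan.

### Seeding

All randomness descends from one root seed through `numpy.random.SeedSequence`
spawn keys. Repetition j of a run uses a child seed that depends only on
(root, j), so the first r′ repetitions of a longer run replicate a shorter
run exactly and any repetition can be replayed in isolation; the same holds
for dataset i of a simulation scenario. Results are therefore independent of
execution order, and serial and (potential) concurrent execution agree.

## Super learner

Both nuisance functions are fit by a cross-validated convex stack. Candidate
learners (the default roster): main-effects logistic regression, binomial
GAMs with B-spline basis dimension 4 and 6 on each continuous covariate
(binary covariates enter linearly; statsmodels `GLMGam`), a single-hidden-layer
neural network with 2 logistic units (weight decay 10⁻⁴, L-BFGS, inputs
standardized), a random forest with 500 trees and minimum leaf size 20, and
the empirical mean. Covariates enter untransformed, so the parametric
candidates are misspecified by design whenever the generating mechanism is
nonlinear. Weights minimize the 10-fold cross-validated negative Bernoulli
log-likelihood over the probability simplex (SLSQP with an analytic gradient;
the solution is floored at the best single candidate, so the ensemble's CV
risk never exceeds any candidate's). Folds are stratified on the outcome;
with very sparse outcomes the fold count drops to the minority-class count so
each fold sees both classes. A candidate that fails to fit is dropped with a
warning; if all fail, or the outcome is (near-)constant in a training pool,
the enclosing repetition is marked failed — the same failure mode that sparse
binary covariates produce in real-data cross-fitting.

A two-candidate fast roster (logistic regression + empirical mean) is used
for smoke tests and desk-scale simulation runs where the full roster's cost
is not warranted.

## Numerical choices

* g truncated to [0.01, 0.99] and q to [0.0005, 0.9995] before the logit;
  the bounds are stability guards, not tuning parameters, and are exposed as
  module constants for sensitivity analysis.
* Fluctuation solved by offset logistic IRLS (statsmodels GLM), tolerance
  10⁻¹⁰, max 100 iterations; non-convergence or separation raises a split
  failure that propagates to repetition failure.
* Candidate probabilities are clipped to [10⁻⁶, 1−10⁻⁶] for log-safety in the
  meta-learner loss.
* GAM spline bases are evaluated with new data clamped to the training range.

## Synthetic data

`generate_dataset` emulates a cardiovascular-prevention study: age ~
Uniform(40, 75) rounded to years; ln(LDL) normal with a mild age trend;
diabetes and frailty from logistic models with quadratic age terms; a
deterministic continuous risk score that is a nonlinear (interaction-bearing)
function of the other covariates; treatment uptake driven mainly by the risk
score (≈25% treated); and outcome risk (≈16%) increasing in the same
covariates with a protective treatment effect (conditional log-OR −0.9 and a
treatment-by-lipid interaction). The true marginal risk difference, obtained
by potential-outcome simulation at 2×10⁶ draws, is ψ ≈ −0.088 (Monte Carlo SE
≈ 0.0003). The crude treated-minus-untreated contrast is ≈ +0.02 — strong
confounding by indication, with the sign reversed relative to the causal
effect. All coefficients sit in one frozen record (`DGMCoefficients`); the
treatment coefficients can be zeroed for null-effect checks.

What the generator does *not* emulate: survey design features, high-
dimensional or sparse proxy covariates, measurement error, and missingness.
Passing tests therefore show correct estimator behaviour under low-dimensional
nonlinear confounding, not performance in high-dimensional registries.

`generate_simple_dataset` is a one-covariate logistic mechanism whose
treatment coefficient is solved (quadrature + bisection) so the marginal risk
difference equals a requested value exactly; it supplies the known truth for
parameter-recovery tests without relying on any simulated truth.

## Simulation harness and performance measures

`run_scenario` simulates S datasets and runs the configured estimators (DCF
over a list of split counts; the non-cross-fit TMLE comparator). Metrics in
`performance`: bias; empirical SE (SD of estimates); average model SE as
√(mean SE²) — the root-mean-square convention of standard simulation-summary
software, with the arithmetic mean as a secondary column; relative % error in
model SE, 100·(modSE/empSE − 1); MSE; coverage of the nominal 95% CI; and
bias-eliminated coverage (CIs evaluated against the mean estimate). Each
metric carries its Monte Carlo standard error (Morris–White–Crowther
formulas; coverage MC SE is exactly √(c(1−c)/S)). Failed rows are excluded
and counted. Zip-plot data (per-dataset CIs ranked by |est − ψ|/SE) are
exported as CSV; plotting stays out of the core.

## Problem sizes used in the shipped checks

The full-scale study design (2000 datasets × r=100 × the six-learner roster)
is cluster-class; the package's own checks run the identical pipeline at desk
scale, a deliberate design choice: parameter recovery uses 50 datasets of
n=3000 with p=5, r=25 and the fast roster; the split/scheme comparison uses
40 datasets of n=3000 with r=10 and the fast roster across Generalization 1
(p = 3, 5, 10) and Generalization 2 (p = 5, 9, with p = 3 shared — the two
schemes are identical there); the reproduction script uses the same sizes. At
this scale the qualitative behaviour (model-SE inflation with p under equal
splits, stable calibration under full data use) is reproducible, while exact
full-scale magnitudes are not expected to transfer.

## Known limitations

* Risk difference only; no risk ratio / odds ratio scales, no continuous
  outcomes, no survey weights.
* No CV-TMLE and no single-cross-fit comparator.
* The Generalization-2 even-p pooling mode re-splits at the record level and
  therefore has no split-labelled role structure to report.
* The influence-curve variance ignores partition noise; the repetition
  median plus between-term absorbs most, but not all, of it — this is
  precisely the calibration behaviour the simulation harness measures.
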