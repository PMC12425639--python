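# dcftmle

Double cross-fitted targeted maximum likelihood estimation (DCF TMLE) of the
average treatment effect — on the risk-difference scale — of a binary
treatment on a binary outcome, for epidemiologists and biostatisticians who
want machine-learning nuisance models *and* honest confidence intervals.

## The method in brief

For covariates **L**, treatment A and outcome Y, the estimand is
ψ = E[Y¹ − Y⁰]. TMLE updates initial super-learner estimates of the
propensity score g(L) = P(A=1|L) and outcome regression q_a(L) = P(Y=1|A=a,L)
through the logistic fluctuation

    logit q*(A,L) = logit q(A,L) + ε·H(A,L),   H = A/g − (1−A)/(1−g),

and reports ψ̂ = mean(q₁* − q₀*) with influence-curve variance. Flexible
learners can invalidate the usual variance theory; **double cross-fitting**
repairs this by training g, training q, and evaluating ψ̂ on three pairwise
*disjoint* splits. With p ≥ 3 splits and r repetitions:

* per repetition, each of the p splits serves once as the estimation split,
  with the roles of the other splits assigned by one of two schemes —
  **equal splits** (Generalization 1: one split per role, cyclic) or
  **full data use** (Generalization 2: the p−1 remaining splits divided
  equally between the two training pools);
* the p split estimates and their variances are averaged within a
  repetition, and the overall estimate/variance are medians across
  repetitions (within + between terms), robust to occasional failed
  repetitions.

Both schemes coincide exactly at p = 3. The nuisance models use a
10-fold-CV super learner (logistic regression, GAMs with basis dimension 4
and 6, a 2-unit neural net, a 500-tree random forest with minimum leaf 20,
and the empirical mean), with covariates supplied as untransformed main
effects. See `docs/methods.md` for the full account.

## Worked example

```python
from dcftmle import generate_dataset, dcf_tmle, tmle_no_crossfit, true_psi, FAST_LIBRARY

truth = true_psi(2_000_000, seed=1)          # potential-outcome simulation
data = generate_dataset(3000, seed=2).records
fit = dcf_tmle(data, p=5, r=10, generalization=2, seed=3, library=FAST_LIBRARY)
print(f"psi true = {truth.psi:.4f}")
print(f"DCF TMLE (p=5, full data use): {fit.ate:.4f}  SE {fit.se:.4f}  "
      f"95% CI [{fit.ci_low:.4f}, {fit.ci_high:.4f}]  "
      f"({fit.n_success}/{fit.n_success + fit.n_failed} repetitions)")
```

prints

```
psi true = -0.0884
DCF TMLE (p=5, full data use): -0.0834  SE 0.0133  95% CI [-0.1094, -0.0573]  (10/10 repetitions)
```

The synthetic cohort emulates a preventive-medication study: the crude
treated-minus-untreated contrast is ≈ +0.02 (treated patients are sicker),
while the causal risk difference is ≈ −0.088; the DCF TMLE recovers the
protective effect with a calibrated interval. The same estimator runs from
the shell:

```bash
dcf-tmle estimate data.csv --p 5 --r 25 --generalization 2 --seed 1 --out summary.csv
dcf-tmle simulate scenario.yaml --out-prefix results/run
```

`estimate` writes one summary row (and a JSON manifest with every repetition
seed); `simulate` runs a Monte Carlo scenario from a YAML config and writes
raw estimates, a performance table (bias, empirical and average model SE,
relative SE error, MSE, coverage, bias-eliminated coverage, with Monte Carlo
SEs) and zip-plot data.

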