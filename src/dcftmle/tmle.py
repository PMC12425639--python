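"""Targeting step of TMLE for the risk difference, and the non-cross-fit estimator.

Given initial nuisance predictions — a propensity score g(L) = P(A=1|L) and
outcome regressions q_a(L) = P(Y=1|A=a,L) — the targeting step fits the
one-parameter logistic fluctuation

    logit q*(A, L) = logit q(A, L) + eps * H(A, L),
    H(A, L) = A / g(L) - (1 - A) / (1 - g(L)),

by maximum likelihood with logit q as offset (the "clever covariate"
regression, single shared eps for both treatment arms).  The plug-in risk
difference is the mean of q1* - q0* over the estimation records, and its
variance is the sample variance of the estimated efficient influence curve

    IC_i = H_i (y_i - q*_{A_i,i}) + (q1*_i - q0*_i) - ate

divided by the effective sample size.  After targeting, the score
mean(H (y - q*)) is zero up to solver tolerance — the defining property of
the update.

Numerical guards: g is truncated to [0.01, 0.99] and q to [0.0005, 0.9995]
before the logit transform.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit, logit

from ._seeding import child_seed
from .learners import DEFAULT_LIBRARY, SuperLearner

G_BOUNDS = (0.01, 0.99)
Q_BOUNDS = (5e-4, 1.0 - 5e-4)


class FluctuationError(RuntimeError):
    """The fluctuation fit did not converge; callers treat the split (and hence
    the enclosing repetition) as failed."""


@dataclass(frozen=True)
class NuisancePredictions:
    """Propensity and outcome predictions aligned to the estimation records."""

    g: np.ndarray
    q0: np.ndarray
    q1: np.ndarray

    def __post_init__(self):
        g, q0, q1 = (np.asarray(v, dtype=float) for v in (self.g, self.q0, self.q1))
        if not (len(g) == len(q0) == len(q1)):
            raise ValueError("g, q0, q1 must have equal length")
        object.__setattr__(self, "g", g)
        object.__setattr__(self, "q0", q0)
        object.__setattr__(self, "q1", q1)

    def bounded(self) -> "NuisancePredictions":
        return NuisancePredictions(
            g=np.clip(self.g, *G_BOUNDS),
            q0=np.clip(self.q0, *Q_BOUNDS),
            q1=np.clip(self.q1, *Q_BOUNDS),
        )


@dataclass(frozen=True)
class SplitEstimate:
    """Risk difference and influence-curve variance from one estimation split."""

    ate_p: float
    var_p: float
    n_p: int
    epsilon: float = float("nan")


def tmle_target(
    y: np.ndarray,
    a: np.ndarray,
    nuis: NuisancePredictions,
    n_variance: int | None = None,
) -> SplitEstimate:
    """Logistic fluctuation of the initial predictions on the estimation split.

    ``n_variance`` is the denominator of the variance estimate.  It defaults
    to the number of estimation records (appropriate when the estimator is
    the one computed on these records alone, e.g. the non-cross-fit TMLE).
    Under cross-fitting, where the final estimate averages the disjoint
    splits' estimates, the caller passes the full sample size so that the
    averaged per-split variances estimate the variance of that average.
    """
    y = np.asarray(y, dtype=float)
    a = np.asarray(a, dtype=float)
    nb = nuis.bounded()
    n_p = len(y)
    if len(a) != n_p or len(nb.g) != n_p:
        raise ValueError("y, a and nuisance predictions must be aligned")

    h1 = 1.0 / nb.g
    h0 = -1.0 / (1.0 - nb.g)
    h = a * h1 + (1.0 - a) * h0
    offset = logit(a * nb.q1 + (1.0 - a) * nb.q0)

    try:
        res = sm.GLM(y, h[:, None], family=sm.families.Binomial(), offset=offset).fit(
            maxiter=100, tol=1e-10
        )
        converged = bool(getattr(res, "converged", True))
        eps = float(res.params[0])
    except Exception as exc:  # perfect separation, singular weights, ...
        raise FluctuationError(f"fluctuation fit failed: {exc}") from exc
    if not converged or not np.isfinite(eps):
        raise FluctuationError("fluctuation fit did not converge")

    q1s = expit(logit(nb.q1) + eps * h1)
    q0s = expit(logit(nb.q0) + eps * h0)
    qas = a * q1s + (1.0 - a) * q0s
    ate_p = float(np.mean(q1s - q0s))
    ic = h * (y - qas) + (q1s - q0s) - ate_p
    denom = int(n_variance) if n_variance is not None else n_p
    var_p = float(np.var(ic, ddof=1) / denom) if n_p > 1 else float("nan")
    return SplitEstimate(ate_p=ate_p, var_p=var_p, n_p=n_p, epsilon=eps)


def targeting_score(y, a, nuis: NuisancePredictions, estimate: SplitEstimate) -> float:
    """Empirical mean of the clever-covariate score H (y - q*) after targeting."""
    y = np.asarray(y, dtype=float)
    a = np.asarray(a, dtype=float)
    nb = nuis.bounded()
    h1, h0 = 1.0 / nb.g, -1.0 / (1.0 - nb.g)
    h = a * h1 + (1.0 - a) * h0
    q1s = expit(logit(nb.q1) + estimate.epsilon * h1)
    q0s = expit(logit(nb.q0) + estimate.epsilon * h0)
    qas = a * q1s + (1.0 - a) * q0s
    return float(np.mean(h * (y - qas)))


def tmle_no_crossfit(
    data: pd.DataFrame,
    outcome: str = "Y",
    treatment: str = "A",
    covariates: list[str] | None = None,
    library=DEFAULT_LIBRARY,
    folds: int = 10,
    seed: int = 0,
):
    """Non-cross-fit TMLE: both nuisances fit by super learner on all records,
    targeting on all records.  Returns a :class:`dcftmle.dcf.DCFResult` with
    r = 1, p = 1 semantics so it is directly comparable to the cross-fit
    estimators."""
    from .dcf import DCFResult  # local import to avoid a cycle

    if covariates is None:
        covariates = [c for c in data.columns if c not in (outcome, treatment)]
    y = data[outcome].to_numpy(dtype=float)
    a = data[treatment].to_numpy(dtype=float)
    X = data[covariates]

    g_fit = SuperLearner(library, folds=folds, seed=child_seed(seed, 0)).fit(X, a)
    Xq = data[covariates + [treatment]]
    q_fit = SuperLearner(library, folds=folds, seed=child_seed(seed, 1)).fit(Xq, y)
    X1 = Xq.copy()
    X1[treatment] = 1.0
    X0 = Xq.copy()
    X0[treatment] = 0.0
    nuis = NuisancePredictions(g=g_fit.predict(X), q0=q_fit.predict(X0), q1=q_fit.predict(X1))
    est = tmle_target(y, a, nuis)
    se = float(np.sqrt(est.var_p))
    return DCFResult(
        ate=est.ate_p,
        var=est.var_p,
        se=se,
        ci_low=est.ate_p - 1.96 * se,
        ci_high=est.ate_p + 1.96 * se,
        n_success=1,
        n_failed=0,
        generalization=0,
        p=1,
        r=1,
        method="tmle_no_crossfit",
    )
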