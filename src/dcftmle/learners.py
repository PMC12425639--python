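"""Candidate learners and the cross-validated super learner.

The super learner is a convex-weighted stack of candidate probability
learners.  Weights are chosen to minimize the 10-fold cross-validated
negative Bernoulli log-likelihood over the probability simplex, the canonical
meta-learning objective for binary outcomes; the surviving candidates are
then refit on the full training set.

The default roster holds six candidates: main-effects logistic regression,
binomial GAMs with spline basis dimension 4 and 6 on each continuous
covariate, a single-hidden-layer neural network with 2 units, a random forest
with 500 trees and a minimum of 20 records per leaf, and the empirical mean.
Covariates are supplied untransformed, so the parametric candidates are
intentionally misspecified whenever the generating mechanism is nonlinear.

Candidates that fail to fit are dropped with a warning; if every candidate
fails, or the outcome is (nearly) constant, a :class:`DegenerateOutcomeError`
is raised so that callers can mark the enclosing cross-fitting repetition as
failed rather than crash.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.optimize import minimize
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.neural_network import MLPClassifier
from statsmodels.gam.api import BSplines, GLMGam

from ._seeding import child_seed

logger = logging.getLogger(__name__)

_PRED_EPS = 1e-6  # log-safety clip for candidate probabilities


class DegenerateOutcomeError(ValueError):
    """Outcome vector unusable for model fitting (constant / near-constant),
    or every candidate learner failed."""


# --------------------------------------------------------------------------
# Candidate learners
# --------------------------------------------------------------------------


class _LogisticMainEffects:
    def fit(self, X: np.ndarray, y: np.ndarray) -> "_LogisticMainEffects":
        self._model = LogisticRegression(C=np.inf, solver="newton-cholesky", max_iter=200)
        self._model.fit(X, y)
        return self

    def predict_proba1(self, X: np.ndarray) -> np.ndarray:
        return self._model.predict_proba(X)[:, 1]


class _BinomialGAM:
    """Binomial GAM: B-spline smooths of the given basis dimension on each
    continuous column, binary columns as linear terms."""

    def __init__(self, df: int):
        self.df = df

    def fit(self, X: np.ndarray, y: np.ndarray) -> "_BinomialGAM":
        n_unique = [np.unique(X[:, j]).size for j in range(X.shape[1])]
        self._smooth_cols = [j for j, k in enumerate(n_unique) if k > self.df]
        self._linear_cols = [j for j in range(X.shape[1]) if j not in self._smooth_cols]
        exog = sm.add_constant(X[:, self._linear_cols], has_constant="add")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            if self._smooth_cols:
                self._smoother = BSplines(
                    X[:, self._smooth_cols],
                    df=[self.df] * len(self._smooth_cols),
                    degree=[3] * len(self._smooth_cols),
                )
                model = GLMGam(
                    y, exog=exog, smoother=self._smoother, family=sm.families.Binomial()
                )
            else:
                self._smoother = None
                model = sm.GLM(y, exog, family=sm.families.Binomial())
            self._res = model.fit()
        return self

    def predict_proba1(self, X: np.ndarray) -> np.ndarray:
        exog = sm.add_constant(X[:, self._linear_cols], has_constant="add")
        if self._smoother is not None:
            # clamp to the training range so the spline basis stays defined
            xs = X[:, self._smooth_cols]
            lo, hi = self._smoother.x.min(axis=0), self._smoother.x.max(axis=0)
            xs = np.clip(xs, lo, hi)
            pred = self._res.predict(exog=exog, exog_smooth=xs)
        else:
            pred = self._res.predict(exog)
        return np.asarray(pred, dtype=float)


class _NeuralNet2:
    def __init__(self, seed: int):
        self.seed = seed

    def fit(self, X: np.ndarray, y: np.ndarray) -> "_NeuralNet2":
        self._mu, self._sigma = X.mean(axis=0), X.std(axis=0)
        self._sigma[self._sigma == 0] = 1.0
        self._model = MLPClassifier(
            hidden_layer_sizes=(2,),
            activation="logistic",
            alpha=1e-4,
            solver="lbfgs",
            max_iter=500,
            random_state=self.seed,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            self._model.fit((X - self._mu) / self._sigma, y)
        return self

    def predict_proba1(self, X: np.ndarray) -> np.ndarray:
        return self._model.predict_proba((X - self._mu) / self._sigma)[:, 1]


class _RandomForest:
    def __init__(self, seed: int):
        self.seed = seed

    def fit(self, X: np.ndarray, y: np.ndarray) -> "_RandomForest":
        self._model = RandomForestClassifier(
            n_estimators=500, min_samples_leaf=20, random_state=self.seed, n_jobs=1
        )
        self._model.fit(X, y)
        return self

    def predict_proba1(self, X: np.ndarray) -> np.ndarray:
        return self._model.predict_proba(X)[:, 1]


class _EmpiricalMean:
    def fit(self, X: np.ndarray, y: np.ndarray) -> "_EmpiricalMean":
        self._mean = float(np.mean(y))
        return self

    def predict_proba1(self, X: np.ndarray) -> np.ndarray:
        return np.full(X.shape[0], self._mean)


LEARNER_REGISTRY: dict[str, Callable[[int], object]] = {
    "logit_main_effects": lambda seed: _LogisticMainEffects(),
    "gam_4_splines": lambda seed: _BinomialGAM(df=4),
    "gam_6_splines": lambda seed: _BinomialGAM(df=6),
    "nnet_2_hidden": lambda seed: _NeuralNet2(seed),
    "random_forest_500_minleaf20": lambda seed: _RandomForest(seed),
    "empirical_mean": lambda seed: _EmpiricalMean(),
}

#: The full candidate roster used for both nuisance models.
DEFAULT_LIBRARY: tuple[str, ...] = (
    "logit_main_effects",
    "gam_4_splines",
    "gam_6_splines",
    "nnet_2_hidden",
    "random_forest_500_minleaf20",
    "empirical_mean",
)

#: A cheap roster for smoke tests and desk-scale simulation runs.
FAST_LIBRARY: tuple[str, ...] = ("logit_main_effects", "empirical_mean")


# --------------------------------------------------------------------------
# Meta-learner
# --------------------------------------------------------------------------


def _bernoulli_loss(p: np.ndarray, y: np.ndarray) -> float:
    p = np.clip(p, _PRED_EPS, 1.0 - _PRED_EPS)
    return float(-np.mean(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)))


def solve_simplex_weights(oof: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Convex weights minimizing CV negative Bernoulli log-likelihood.

    ``oof`` is an (n, K) matrix of out-of-fold candidate predictions.
    """
    n, k = oof.shape
    if k == 1:
        return np.array([1.0])
    oof = np.clip(oof, _PRED_EPS, 1.0 - _PRED_EPS)

    def loss(w: np.ndarray) -> float:
        return _bernoulli_loss(oof @ w, y)

    def grad(w: np.ndarray) -> np.ndarray:
        p = np.clip(oof @ w, _PRED_EPS, 1.0 - _PRED_EPS)
        return -(oof.T @ (y / p - (1.0 - y) / (1.0 - p))) / n

    w0 = np.full(k, 1.0 / k)
    res = minimize(
        loss,
        w0,
        jac=grad,
        method="SLSQP",
        bounds=[(0.0, 1.0)] * k,
        constraints=[{"type": "eq", "fun": lambda w: w.sum() - 1.0}],
        options={"maxiter": 200, "ftol": 1e-12},
    )
    w = np.clip(res.x, 0.0, None)
    w /= w.sum()
    # never do worse than the best single candidate
    best = int(np.argmin([_bernoulli_loss(oof[:, j], y) for j in range(k)]))
    e_best = np.eye(k)[best]
    if loss(e_best) < loss(w):
        w = e_best
    return w


@dataclass
class SuperLearnerFit:
    """Fitted ensemble: surviving candidate names, simplex weights, CV info."""

    names: tuple[str, ...]
    weights: np.ndarray
    cv_risks: np.ndarray  # per-candidate CV loss
    ensemble_cv_risk: float
    models: list = field(repr=False, default_factory=list)
    columns: tuple[str, ...] = ()

    def predict(self, X_new: pd.DataFrame) -> np.ndarray:
        """Weighted ensemble probabilities on new data."""
        if isinstance(X_new, pd.DataFrame):
            missing = [c for c in self.columns if c not in X_new.columns]
            if missing:
                raise KeyError(f"missing training columns: {missing}")
            Xm = X_new[list(self.columns)].to_numpy(dtype=float)
        else:
            Xm = np.asarray(X_new, dtype=float)
            if Xm.shape[1] != len(self.columns):
                raise KeyError(
                    f"expected {len(self.columns)} columns, got {Xm.shape[1]}"
                )
        preds = np.column_stack([m.predict_proba1(Xm) for m in self.models])
        return np.clip(preds @ self.weights, _PRED_EPS, 1.0 - _PRED_EPS)


class SuperLearner:
    """10-fold cross-validated convex stack of candidate probability learners."""

    def __init__(self, library: Sequence[str] = DEFAULT_LIBRARY, folds: int = 10, seed: int = 0):
        unknown = [name for name in library if name not in LEARNER_REGISTRY]
        if unknown:
            raise ValueError(f"unknown learners: {unknown}")
        if not library:
            raise ValueError("learner library is empty")
        self.library = tuple(library)
        self.folds = int(folds)
        self.seed = int(seed)

    def fit(self, X: pd.DataFrame, y: np.ndarray) -> SuperLearnerFit:
        if isinstance(X, pd.DataFrame):
            columns = tuple(X.columns)
            Xm = X.to_numpy(dtype=float)
        else:
            Xm = np.asarray(X, dtype=float)
            columns = tuple(f"x{j}" for j in range(Xm.shape[1]))
        y = np.asarray(y, dtype=float)
        n = Xm.shape[0]
        if n < self.folds:
            raise ValueError(f"need at least {self.folds} records, got {n}")
        n_minority = int(min(y.sum(), n - y.sum()))
        if n_minority < 2:
            raise DegenerateOutcomeError(
                "outcome is constant or near-constant; cannot cross-validate"
            )
        # folds are stratified on y; with very sparse outcomes the fold count
        # drops to the minority count so every fold sees both classes
        n_folds = min(self.folds, n_minority)
        skf = StratifiedKFold(
            n_splits=n_folds, shuffle=True, random_state=child_seed(self.seed, 0)
        )

        oof = np.full((n, len(self.library)), np.nan)
        alive = list(range(len(self.library)))
        for tr, te in skf.split(Xm, y):
            for j in list(alive):
                try:
                    model = LEARNER_REGISTRY[self.library[j]](child_seed(self.seed, 1, j))
                    model.fit(Xm[tr], y[tr])
                    oof[te, j] = model.predict_proba1(Xm[te])
                except Exception as exc:  # noqa: BLE001 - candidate failure policy
                    logger.warning("candidate %s failed in CV: %s", self.library[j], exc)
                    alive.remove(j)

        models, names, keep = [], [], []
        for j in alive:
            try:
                model = LEARNER_REGISTRY[self.library[j]](child_seed(self.seed, 1, j))
                model.fit(Xm, y)
                models.append(model)
                names.append(self.library[j])
                keep.append(j)
            except Exception as exc:  # noqa: BLE001
                logger.warning("candidate %s failed on refit: %s", self.library[j], exc)
        if not models:
            raise DegenerateOutcomeError("all candidate learners failed to fit")

        oof = np.clip(oof[:, keep], _PRED_EPS, 1.0 - _PRED_EPS)
        weights = solve_simplex_weights(oof, y)
        cv_risks = np.array([_bernoulli_loss(oof[:, j], y) for j in range(len(keep))])
        return SuperLearnerFit(
            names=tuple(names),
            weights=weights,
            cv_risks=cv_risks,
            ensemble_cv_risk=_bernoulli_loss(oof @ weights, y),
            models=models,
            columns=columns,
        )
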