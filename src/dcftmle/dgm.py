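"""Synthetic observational data with known causal truth.

Two generators are provided.

``generate_dataset`` emulates a cardiovascular-prevention setting: five
baseline covariates (age in years, natural-log LDL cholesterol, a diabetes
indicator, a frailty indicator and a continuous risk score), a binary
treatment (preventive medication) taken preferentially by higher-risk
patients, and a binary outcome whose risk rises with the same covariates while
the treatment is protective.  The functional forms are deliberately nonlinear
(quadratic age terms, an age-by-lipid interaction, a treatment-by-lipid
interaction, and a risk score that is itself a nonlinear function of the other
covariates), so that nuisance models supplied with untransformed main effects
are misspecified and data-adaptive learners are genuinely needed.  The true
marginal risk difference psi = E[Y1 - Y0] has no closed form and is obtained
by large-sample potential-outcome simulation (:func:`true_psi`).

``generate_simple_dataset`` is a one-covariate logistic mechanism whose
marginal risk difference is fixed exactly by numerical integration; it exists
for parameter-recovery tests where the truth must be known independently of
any simulation.

All coefficients of the main mechanism live in :class:`DGMCoefficients` so
that tests can, e.g., zero the treatment coefficient to obtain a null effect.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.integrate import quad
from scipy.optimize import brentq
from scipy.special import expit

from ._seeding import rng_from

COVARIATE_COLUMNS = ["age", "ldl_log", "diabetes", "frailty", "risk_score"]
DATASET_COLUMNS = ["Y", "A"] + COVARIATE_COLUMNS

_LDL_REF = float(np.log(115.0))  # reference ln(LDL mg/dL) used to centre lipid terms
_AGE_REF = 55.0


@dataclass(frozen=True)
class DGMCoefficients:
    """Coefficients of the main data-generating mechanism (log-odds scale).

    ``treatment_log_or`` is the conditional log odds ratio of the treatment in
    the outcome model; setting it (and ``treatment_ldl_interaction``) to zero
    yields an exact null effect.
    """

    # ln(LDL) | age
    ldl_mean: float = _LDL_REF
    ldl_age_slope: float = 0.0025
    ldl_sd: float = 0.18
    # diabetes | age, ldl
    diabetes_intercept: float = -2.1
    diabetes_age: float = 0.05
    diabetes_ldl: float = 0.8
    # frailty | age, diabetes (quadratic in age)
    frailty_intercept: float = -2.3
    frailty_age: float = 0.06
    frailty_age2: float = 0.0015
    frailty_diabetes: float = 0.6
    # risk score: deterministic nonlinear summary of the other covariates
    risk_intercept: float = -1.0
    risk_age: float = 0.07
    risk_ldl: float = 1.4
    risk_diabetes: float = 0.9
    risk_frailty: float = 1.1
    risk_age_ldl: float = 0.045
    # treatment | L
    treat_intercept: float = -1.4
    treat_risk: float = 2.2
    treat_age: float = 0.03
    treat_diabetes: float = 0.6
    treat_ldl: float = 0.4
    # outcome | A, L
    outcome_intercept: float = -2.1
    treatment_log_or: float = -0.9
    outcome_risk: float = 2.8
    outcome_age: float = 0.035
    outcome_diabetes: float = 0.6
    outcome_frailty: float = 0.7
    outcome_ldl: float = 0.5
    treatment_ldl_interaction: float = -0.3

    def null_effect(self) -> "DGMCoefficients":
        """The same mechanism with the treatment's effect on the outcome removed."""
        return replace(self, treatment_log_or=0.0, treatment_ldl_interaction=0.0)


DEFAULT_COEFFICIENTS = DGMCoefficients()


@dataclass(frozen=True)
class SimulatedDataset:
    """One generated observational dataset and the seed that produced it."""

    records: pd.DataFrame
    n: int
    seed: int

    @property
    def covariates(self) -> pd.DataFrame:
        return self.records[COVARIATE_COLUMNS]


@dataclass(frozen=True)
class TruthRecord:
    """True marginal risk difference and its Monte Carlo uncertainty."""

    psi: float
    n_truth: int
    mc_se_truth: float


def _draw_covariates(rng: np.random.Generator, n: int, c: DGMCoefficients) -> pd.DataFrame:
    age = np.round(rng.uniform(40.0, 75.0, size=n))
    age_c = age - _AGE_REF
    ldl_log = rng.normal(c.ldl_mean + c.ldl_age_slope * age_c, c.ldl_sd, size=n)
    ldl_c = ldl_log - _LDL_REF
    diabetes = rng.binomial(
        1, expit(c.diabetes_intercept + c.diabetes_age * age_c + c.diabetes_ldl * ldl_c)
    )
    frailty = rng.binomial(
        1,
        expit(
            c.frailty_intercept
            + c.frailty_age * age_c
            + c.frailty_age2 * age_c**2
            + c.frailty_diabetes * diabetes
        ),
    )
    risk_score = expit(
        c.risk_intercept
        + c.risk_age * age_c
        + c.risk_ldl * ldl_c
        + c.risk_diabetes * diabetes
        + c.risk_frailty * frailty
        + c.risk_age_ldl * age_c * ldl_c
    )
    return pd.DataFrame(
        {
            "age": age,
            "ldl_log": ldl_log,
            "diabetes": diabetes,
            "frailty": frailty,
            "risk_score": risk_score,
        }
    )


def treatment_probability(L: pd.DataFrame, c: DGMCoefficients = DEFAULT_COEFFICIENTS) -> np.ndarray:
    """True propensity score P(A=1 | L)."""
    return expit(
        c.treat_intercept
        + c.treat_risk * (L["risk_score"].to_numpy() - 0.4)
        + c.treat_age * (L["age"].to_numpy() - _AGE_REF)
        + c.treat_diabetes * L["diabetes"].to_numpy()
        + c.treat_ldl * (L["ldl_log"].to_numpy() - _LDL_REF)
    )


def outcome_probability(
    L: pd.DataFrame, a: np.ndarray | int, c: DGMCoefficients = DEFAULT_COEFFICIENTS
) -> np.ndarray:
    """True outcome risk P(Y=1 | A=a, L)."""
    a = np.asarray(a, dtype=float)
    ldl_c = L["ldl_log"].to_numpy() - _LDL_REF
    return expit(
        c.outcome_intercept
        + c.treatment_log_or * a
        + c.outcome_risk * (L["risk_score"].to_numpy() - 0.4)
        + c.outcome_age * (L["age"].to_numpy() - _AGE_REF)
        + c.outcome_diabetes * L["diabetes"].to_numpy()
        + c.outcome_frailty * L["frailty"].to_numpy()
        + c.outcome_ldl * ldl_c
        + c.treatment_ldl_interaction * a * ldl_c
    )


def generate_dataset(
    n: int, seed: int, coefficients: DGMCoefficients = DEFAULT_COEFFICIENTS
) -> SimulatedDataset:
    """Generate ``n`` observational records (Y, A, five covariates).

    Deterministic in ``seed``: the same seed yields an element-wise identical
    table.
    """
    if n < 1:
        raise ValueError(f"n must be a positive integer, got {n}")
    rng = rng_from(seed, 0)
    L = _draw_covariates(rng, n, coefficients)
    A = rng.binomial(1, treatment_probability(L, coefficients))
    Y = rng.binomial(1, outcome_probability(L, A, coefficients))
    records = pd.DataFrame({"Y": Y, "A": A}).join(L)[DATASET_COLUMNS]
    return SimulatedDataset(records=records, n=n, seed=int(seed))


def true_psi(
    n_truth: int, seed: int, coefficients: DGMCoefficients = DEFAULT_COEFFICIENTS
) -> TruthRecord:
    """True marginal risk difference by large-sample potential-outcome simulation.

    Draws ``n_truth`` covariate vectors, draws both potential outcomes
    (independently) from their conditional laws, and returns
    ``psi = mean(Y1 - Y0)`` with its Monte Carlo standard error.  ``n_truth``
    of 10^6 or more is recommended for a stable third decimal.
    """
    if n_truth < 1:
        raise ValueError(f"n_truth must be a positive integer, got {n_truth}")
    rng = rng_from(seed, 1)
    L = _draw_covariates(rng, n_truth, coefficients)
    y1 = rng.binomial(1, outcome_probability(L, 1, coefficients))
    y0 = rng.binomial(1, outcome_probability(L, 0, coefficients))
    diff = y1.astype(float) - y0.astype(float)
    psi = float(diff.mean())
    mc_se = float(diff.std(ddof=1) / np.sqrt(n_truth)) if n_truth > 1 else float("nan")
    return TruthRecord(psi=psi, n_truth=int(n_truth), mc_se_truth=mc_se)


# --------------------------------------------------------------------------
# Closed-form test mechanism: one uniform covariate, logistic models, exact psi
# --------------------------------------------------------------------------

_SIMPLE_OUTCOME_INTERCEPT = -1.0
_SIMPLE_OUTCOME_SLOPE = 1.5
_SIMPLE_TREAT_INTERCEPT = -0.5
_SIMPLE_TREAT_SLOPE = 1.0


def simple_propensity(u: np.ndarray) -> np.ndarray:
    """True propensity of the simple mechanism, P(A=1 | U=u)."""
    return expit(_SIMPLE_TREAT_INTERCEPT + _SIMPLE_TREAT_SLOPE * np.asarray(u, dtype=float))


def _simple_theta(effect: float) -> float:
    """Treatment log-odds coefficient giving marginal risk difference ``effect``.

    Solves  integral_0^1 [expit(a + b u + theta) - expit(a + b u)] du = effect
    by bisection; the integral is evaluated with adaptive quadrature.
    """

    def marginal_rd(theta: float) -> float:
        val, _ = quad(
            lambda u: expit(_SIMPLE_OUTCOME_INTERCEPT + _SIMPLE_OUTCOME_SLOPE * u + theta)
            - expit(_SIMPLE_OUTCOME_INTERCEPT + _SIMPLE_OUTCOME_SLOPE * u),
            0.0,
            1.0,
        )
        return val

    lo, hi = -30.0, 30.0
    if not marginal_rd(lo) < effect < marginal_rd(hi):
        raise ValueError(f"effect={effect} is not attainable by this mechanism")
    return float(brentq(lambda t: marginal_rd(t) - effect, lo, hi, xtol=1e-12))


def simple_outcome_probability(u: np.ndarray, a: np.ndarray | int, effect: float) -> np.ndarray:
    """True outcome risk of the simple mechanism, P(Y=1 | A=a, U=u)."""
    theta = _simple_theta(effect)
    u = np.asarray(u, dtype=float)
    a = np.asarray(a, dtype=float)
    return expit(_SIMPLE_OUTCOME_INTERCEPT + _SIMPLE_OUTCOME_SLOPE * u + theta * a)


def simple_true_psi(effect: float) -> float:
    """The simple mechanism's marginal risk difference (equal to ``effect`` by
    construction; the treatment coefficient is solved so that the numerically
    integrated potential-outcome contrast matches it)."""
    _simple_theta(effect)  # validates attainability
    return float(effect)


def generate_simple_dataset(n: int, seed: int, effect: float) -> SimulatedDataset:
    """One-covariate confounded dataset with known marginal risk difference.

    U ~ Uniform(0,1) confounds a logistic treatment model and a logistic
    outcome model whose treatment coefficient is solved numerically so that
    E[Y1 - Y0] equals ``effect`` exactly.
    """
    if n < 1:
        raise ValueError(f"n must be a positive integer, got {n}")
    if not -1.0 < effect < 1.0:
        raise ValueError(f"effect must lie in (-1, 1), got {effect}")
    theta = _simple_theta(effect)
    rng = rng_from(seed, 2)
    u = rng.uniform(0.0, 1.0, size=n)
    A = rng.binomial(1, simple_propensity(u))
    p_y = expit(_SIMPLE_OUTCOME_INTERCEPT + _SIMPLE_OUTCOME_SLOPE * u + theta * A)
    Y = rng.binomial(1, p_y)
    records = pd.DataFrame({"Y": Y, "A": A, "u": u})
    return SimulatedDataset(records=records, n=n, seed=int(seed))


# --------------------------------------------------------------------------
# CSV round trip
# --------------------------------------------------------------------------


def write_dataset_csv(dataset: SimulatedDataset, path) -> None:
    """Write the records as CSV with header Y,A,age,ldl_log,diabetes,frailty,risk_score."""
    dataset.records.to_csv(path, index=False)


def read_dataset_csv(path) -> pd.DataFrame:
    """Read a dataset CSV written by :func:`write_dataset_csv` (or any CSV with
    binary Y and A columns), validating the outcome and treatment columns."""
    df = pd.read_csv(path)
    for col in ("Y", "A"):
        if col not in df.columns:
            raise ValueError(f"missing required column {col!r}")
        vals = df[col].to_numpy()
        if not np.isin(vals, (0, 1)).all():
            raise ValueError(f"column {col!r} must be binary 0/1")
    if df.isna().any().any():
        raise ValueError("dataset contains missing values")
    return df
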