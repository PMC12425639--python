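"""Double cross-fitting: split planning, role assignment, repetitions, aggregation.

One repetition partitions the records into ``p`` non-overlapping, near
equal-sized splits and forms ``p`` role triples (estimation split s,
propensity-training splits P_s, outcome-training splits Q_s), with the three
index sets pairwise disjoint in every triple — the defining discordance of
double cross-fitting.  Two role schemes are supported:

* **Generalization 1 (equal splits)** — one split per role, assigned
  cyclically: P_s = {s-1}, Q_s = {s-2} (labels mod p).  For p > 3 the
  remaining p-3 splits are unused within any single triple.
* **Generalization 2 (full data use)** — the p-1 non-estimation splits are
  divided alternately (in cyclic order s-1, s-2, ...) between the propensity
  and outcome training pools, so every record is used in every triple.
  Requires odd p so the pools are equal; with ``pool_even_splits=True`` an
  even p is handled by pooling the p-1 remaining splits' records and
  re-splitting them into two equal halves.

Both schemes coincide exactly at p = 3, so runs with shared seeds are
bitwise identical there.

Within a repetition the p split estimates are averaged (point estimate and
influence-curve variance alike).  Across ``r`` repetitions the overall
estimate is the median of the repetition estimates and the overall variance
the median of within + between terms, var_r + (ate_r - ate)^2.  Statistical
failures inside a repetition (degenerate outcome in a training pool,
non-convergent fluctuation) mark that repetition failed rather than raising;
failed repetitions are excluded from the medians.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from ._seeding import child_seed, rng_from
from .learners import DEFAULT_LIBRARY, DegenerateOutcomeError, SuperLearner
from .tmle import FluctuationError, NuisancePredictions, tmle_target


class AllRepetitionsFailedError(RuntimeError):
    """No repetition produced an estimate; nothing to aggregate."""


@dataclass(frozen=True)
class RoleTriple:
    """Estimation split and its propensity / outcome training split sets (1-based)."""

    estimation: int
    propensity: tuple[int, ...]
    outcome: tuple[int, ...]


@dataclass(frozen=True)
class SplitPlan:
    """A partition of record indices into p splits plus per-split role triples."""

    p: int
    assignment: np.ndarray  # record index -> split label in 1..p
    roles: tuple[RoleTriple, ...]

    def indices(self, splits: Sequence[int]) -> np.ndarray:
        return np.flatnonzero(np.isin(self.assignment, splits))

    def validate(self) -> None:
        sizes = np.bincount(self.assignment, minlength=self.p + 1)[1:]
        if sizes.max() - sizes.min() > 1:
            raise AssertionError("split sizes differ by more than 1")
        for t in self.roles:
            sets = [{t.estimation}, set(t.propensity), set(t.outcome)]
            for i in range(3):
                for j in range(i + 1, 3):
                    if sets[i] & sets[j]:
                        raise AssertionError(f"role sets overlap in triple {t}")


def make_splits(n: int, p: int, seed: int) -> np.ndarray:
    """Uniformly random partition of n records into p splits (labels 1..p)
    whose sizes differ by at most one."""
    if p < 3:
        raise ValueError("double cross-fitting needs at least 3 splits")
    if p > n:
        raise ValueError(f"cannot make {p} splits from {n} records")
    rng = rng_from(seed, 0)
    perm = rng.permutation(n)
    labels = np.empty(n, dtype=np.int64)
    base, extra = divmod(n, p)
    start = 0
    for s in range(1, p + 1):
        size = base + (1 if s <= extra else 0)
        labels[perm[start : start + size]] = s
        start += size
    return labels


def _mod1(x: int, p: int) -> int:
    """x reduced to 1..p."""
    return (x - 1) % p + 1


def roles_gen1(p: int) -> tuple[RoleTriple, ...]:
    """Equal-splits roles: for estimation split s, P = {s-1}, Q = {s-2}."""
    if p < 3:
        raise ValueError("need p >= 3")
    return tuple(
        RoleTriple(estimation=s, propensity=(_mod1(s - 1, p),), outcome=(_mod1(s - 2, p),))
        for s in range(1, p + 1)
    )


def roles_gen2(p: int) -> tuple[RoleTriple, ...]:
    """Full-data roles: the p-1 non-estimation splits, taken in cyclic order
    s-1, s-2, ..., alternate between the propensity and outcome pools
    (starting with the propensity pool).  Coincides with
    :func:`roles_gen1` at p = 3.  Requires odd p for equal pools."""
    if p < 3:
        raise ValueError("need p >= 3")
    if p % 2 == 0:
        raise ValueError(
            "generalization 2 needs an odd number of splits for equal training "
            "pools; use pool_even_splits=True to pool and re-split instead"
        )
    triples = []
    for s in range(1, p + 1):
        order = [_mod1(s - k, p) for k in range(1, p)]
        triples.append(
            RoleTriple(
                estimation=s,
                propensity=tuple(order[0::2]),
                outcome=tuple(order[1::2]),
            )
        )
    return tuple(triples)


def build_plan(n: int, p: int, generalization: int, seed: int) -> SplitPlan:
    """Random split assignment plus role triples for the chosen scheme."""
    if generalization not in (1, 2):
        raise ValueError("generalization must be 1 or 2")
    roles = roles_gen1(p) if generalization == 1 else roles_gen2(p)
    plan = SplitPlan(p=p, assignment=make_splits(n, p, seed), roles=roles)
    plan.validate()
    return plan


@dataclass(frozen=True)
class RepetitionEstimate:
    """One repetition: the average of the p split estimates, or a failure marker."""

    status: str  # "success" | "failed"
    ate_r: float = float("nan")
    var_r: float = float("nan")
    seed: int = -1
    reason: str = ""

    @property
    def ok(self) -> bool:
        return self.status == "success"


@dataclass(frozen=True)
class DCFResult:
    """Overall estimate: medians over successful repetitions, with 95% CI."""

    ate: float
    var: float
    se: float
    ci_low: float
    ci_high: float
    n_success: int
    n_failed: int
    generalization: int
    p: int
    r: int
    method: str = "dcf_tmle"
    repetitions: tuple[RepetitionEstimate, ...] = field(default=(), repr=False)

    def summary_row(self) -> dict:
        return {
            "method": self.method,
            "generalization": self.generalization,
            "p": self.p,
            "r": self.r,
            "ate": self.ate,
            "se": self.se,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "n_success": self.n_success,
            "n_failed": self.n_failed,
        }


def run_repetition(
    data: pd.DataFrame,
    p: int,
    generalization: int,
    seed: int,
    outcome: str = "Y",
    treatment: str = "A",
    covariates: list[str] | None = None,
    library=DEFAULT_LIBRARY,
    folds: int = 10,
    pool_even_splits: bool = False,
) -> RepetitionEstimate:
    """One full double cross-fitting repetition.

    Statistical failures (degenerate outcome in a training pool, fluctuation
    non-convergence) are encoded in the returned status, never raised.
    """
    if covariates is None:
        covariates = [c for c in data.columns if c not in (outcome, treatment)]
    n = len(data)
    y_all = data[outcome].to_numpy(dtype=float)
    a_all = data[treatment].to_numpy(dtype=float)
    X = data[covariates].reset_index(drop=True)
    Xq = data[covariates + [treatment]].reset_index(drop=True)

    even_gen2 = generalization == 2 and p % 2 == 0
    if even_gen2 and not pool_even_splits:
        raise ValueError(
            "generalization 2 with an even number of splits requires pool_even_splits=True"
        )

    try:
        if even_gen2:
            assignment = make_splits(n, p, seed)
            plan = SplitPlan(p=p, assignment=assignment, roles=roles_gen1(p))  # roles unused
            triples = [RoleTriple(estimation=s, propensity=(), outcome=()) for s in range(1, p + 1)]
            pool_rng = rng_from(seed, 3)
        else:
            plan = build_plan(n, p, generalization, seed)
            triples = list(plan.roles)

        ates, variances = [], []
        for k, triple in enumerate(triples):
            est_idx = plan.indices([triple.estimation])
            if even_gen2:
                rest = np.flatnonzero(plan.assignment != triple.estimation)
                rest = pool_rng.permutation(rest)
                half = len(rest) // 2
                g_idx, q_idx = rest[:half], rest[half:]
            else:
                g_idx = plan.indices(triple.propensity)
                q_idx = plan.indices(triple.outcome)

            g_sl = SuperLearner(library, folds=folds, seed=child_seed(seed, 1, k, 0))
            g_fit = g_sl.fit(X.iloc[g_idx], a_all[g_idx])
            q_sl = SuperLearner(library, folds=folds, seed=child_seed(seed, 1, k, 1))
            q_fit = q_sl.fit(Xq.iloc[q_idx], y_all[q_idx])

            Xq_est = Xq.iloc[est_idx]
            X1 = Xq_est.copy()
            X1[treatment] = 1.0
            X0 = Xq_est.copy()
            X0[treatment] = 0.0
            nuis = NuisancePredictions(
                g=g_fit.predict(X.iloc[est_idx]),
                q0=q_fit.predict(X0),
                q1=q_fit.predict(X1),
            )
            est = tmle_target(y_all[est_idx], a_all[est_idx], nuis, n_variance=n)
            ates.append(est.ate_p)
            variances.append(est.var_p)
    except (DegenerateOutcomeError, FluctuationError) as exc:
        return RepetitionEstimate(status="failed", seed=seed, reason=str(exc))

    return RepetitionEstimate(
        status="success",
        ate_r=float(np.mean(ates)),
        var_r=float(np.mean(variances)),
        seed=seed,
    )


def aggregate(reps: Sequence[RepetitionEstimate], **meta) -> DCFResult:
    """Median aggregation over successful repetitions.

    ate = median(ate_r); var = median(var_r + (ate_r - ate)^2); the between
    term is centred at the overall median.  Failed repetitions are counted
    but excluded.
    """
    ok = [rep for rep in reps if rep.ok]
    n_failed = len(reps) - len(ok)
    if not ok:
        raise AllRepetitionsFailedError("no successful repetitions to aggregate")
    ate_rs = np.array([rep.ate_r for rep in ok])
    var_rs = np.array([rep.var_r for rep in ok])
    ate = float(np.median(ate_rs))
    var = float(np.median(var_rs + (ate_rs - ate) ** 2))
    se = float(np.sqrt(var))
    return DCFResult(
        ate=ate,
        var=var,
        se=se,
        ci_low=ate - 1.96 * se,
        ci_high=ate + 1.96 * se,
        n_success=len(ok),
        n_failed=n_failed,
        generalization=meta.get("generalization", 0),
        p=meta.get("p", 0),
        r=len(reps),
        method=meta.get("method", "dcf_tmle"),
        repetitions=tuple(reps),
    )


def dcf_tmle(
    data: pd.DataFrame,
    p: int = 3,
    r: int = 100,
    generalization: int = 1,
    seed: int = 0,
    outcome: str = "Y",
    treatment: str = "A",
    covariates: list[str] | None = None,
    library=DEFAULT_LIBRARY,
    folds: int = 10,
    pool_even_splits: bool = False,
    retry_failed: bool = False,
    max_retries: int = 5,
) -> DCFResult:
    """Double cross-fitted TMLE of the risk difference.

    Repetition j uses the child seed derived from (seed, j), so the first r'
    repetitions of a longer run reproduce a shorter run exactly, and
    individual repetitions can be replayed in isolation.  With
    ``retry_failed=True`` a failed repetition is re-drawn (fresh child seed)
    up to ``max_retries`` times; the default drops failures instead.
    """
    if r < 1:
        raise ValueError("need at least one repetition")
    reps = []
    for j in range(r):
        rep = run_repetition(
            data,
            p=p,
            generalization=generalization,
            seed=child_seed(seed, j, 0),
            outcome=outcome,
            treatment=treatment,
            covariates=covariates,
            library=library,
            folds=folds,
            pool_even_splits=pool_even_splits,
        )
        if retry_failed:
            attempt = 1
            while not rep.ok and attempt <= max_retries:
                rep = run_repetition(
                    data,
                    p=p,
                    generalization=generalization,
                    seed=child_seed(seed, j, attempt),
                    outcome=outcome,
                    treatment=treatment,
                    covariates=covariates,
                    library=library,
                    folds=folds,
                    pool_even_splits=pool_even_splits,
                )
                attempt += 1
        reps.append(rep)
    return aggregate(reps, generalization=generalization, p=p, method="dcf_tmle")
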