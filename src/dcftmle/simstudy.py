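"""Monte Carlo harness and simulation performance metrics.

``run_scenario`` generates S independent datasets (child seeds derived from
the scenario root seed, so dataset i is reproducible in isolation and the
repetition streams of shorter runs are prefixes of longer ones) and runs the
configured estimators.  ``performance`` summarises the raw estimates with the
standard simulation-study measures:

* bias = mean(est) - psi
* empirical SE = sd(est) over datasets
* average model SE = sqrt(mean(se^2)) (the root-mean-square convention used
  by standard simulation-summary software; the arithmetic mean is reported as
  a secondary column)
* relative % error in model SE = 100 (avg model SE / empirical SE - 1)
* MSE, coverage of the 95% CI for psi, bias-eliminated coverage (CIs
  evaluated against mean(est) instead of psi)

with the matching Monte Carlo standard errors.  Flagged (failed) datasets are
excluded from all metrics and counted.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from ._seeding import child_seed
from .dcf import AllRepetitionsFailedError, dcf_tmle
from .dgm import generate_dataset, generate_simple_dataset
from .learners import DEFAULT_LIBRARY
from .tmle import tmle_no_crossfit

RAW_COLUMNS = [
    "sim",
    "estimator",
    "generalization",
    "p",
    "r",
    "seed",
    "status",
    "estimate",
    "se",
    "ci_low",
    "ci_high",
    "n_success",
    "n_failed",
]


@dataclass
class ScenarioConfig:
    """One simulation scenario: sample size, split counts, scheme, repetitions."""

    n: int = 3000
    p: tuple[int, ...] = (3,)
    generalization: int = 1
    r: int = 100
    n_sims: int = 2000
    seed: int = 0
    learners: tuple[str, ...] = tuple(DEFAULT_LIBRARY)
    estimators: tuple[str, ...] = ("dcf",)
    dgm: str = "main"  # "main" | "simple"
    simple_effect: float = 0.10
    folds: int = 10

    def __post_init__(self):
        self.p = tuple(int(v) for v in (self.p if hasattr(self.p, "__iter__") else (self.p,)))
        self.learners = tuple(self.learners)
        self.estimators = tuple(self.estimators)
        if self.n_sims < 1:
            raise ValueError("n_sims must be positive")
        if self.n < 1 or self.r < 1:
            raise ValueError("n and r must be positive")
        if any(v < 3 for v in self.p):
            raise ValueError("split counts must be >= 3")
        if self.generalization not in (1, 2):
            raise ValueError("generalization must be 1 or 2")
        unknown = set(self.estimators) - {"dcf", "no_crossfit"}
        if unknown:
            raise ValueError(f"unknown estimators: {sorted(unknown)}")
        if self.dgm not in ("main", "simple"):
            raise ValueError("dgm must be 'main' or 'simple'")

    @classmethod
    def from_yaml(cls, path) -> "ScenarioConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


def _generate(cfg: ScenarioConfig, data_seed: int):
    if cfg.dgm == "simple":
        return generate_simple_dataset(cfg.n, data_seed, cfg.simple_effect)
    return generate_dataset(cfg.n, data_seed)


def run_scenario(
    cfg: ScenarioConfig,
    out_csv: str | Path | None = None,
    progress: bool = False,
) -> pd.DataFrame:
    """Run the scenario, one row per dataset x estimator (x split count for dcf).

    If ``out_csv`` exists, rows already present there are skipped and the file
    is extended, making interrupted runs resumable with identical results
    (each row depends only on its own child seeds).
    """
    done: set[tuple] = set()
    rows: list[dict] = []
    out_path = Path(out_csv) if out_csv is not None else None
    if out_path is not None and out_path.exists():
        prev = pd.read_csv(out_path)
        rows = prev.to_dict("records")
        done = {(int(t.sim), t.estimator, int(t.p)) for t in prev.itertuples()}

    for i in range(cfg.n_sims):
        data_seed = child_seed(cfg.seed, i, 0)
        est_seed = child_seed(cfg.seed, i, 1)
        dataset = None
        for estimator in cfg.estimators:
            p_values = cfg.p if estimator == "dcf" else (1,)
            for p in p_values:
                key = (i, estimator, p)
                if key in done:
                    continue
                if dataset is None:
                    dataset = _generate(cfg, data_seed)
                row = {
                    "sim": i,
                    "estimator": estimator,
                    "generalization": cfg.generalization if estimator == "dcf" else 0,
                    "p": p,
                    "r": cfg.r if estimator == "dcf" else 1,
                    "seed": data_seed,
                    "status": "ok",
                    "estimate": np.nan,
                    "se": np.nan,
                    "ci_low": np.nan,
                    "ci_high": np.nan,
                    "n_success": 0,
                    "n_failed": 0,
                }
                try:
                    if estimator == "dcf":
                        res = dcf_tmle(
                            dataset.records,
                            p=p,
                            r=cfg.r,
                            generalization=cfg.generalization,
                            seed=child_seed(est_seed, p),
                            library=cfg.learners,
                            folds=cfg.folds,
                        )
                    else:
                        res = tmle_no_crossfit(
                            dataset.records,
                            library=cfg.learners,
                            folds=cfg.folds,
                            seed=child_seed(est_seed, 0, 0),
                        )
                    row.update(
                        estimate=res.ate,
                        se=res.se,
                        ci_low=res.ci_low,
                        ci_high=res.ci_high,
                        n_success=res.n_success,
                        n_failed=res.n_failed,
                    )
                except AllRepetitionsFailedError as exc:
                    row.update(status=f"failed: {exc}")
                rows.append(row)
                if out_path is not None:
                    pd.DataFrame(rows, columns=RAW_COLUMNS).to_csv(out_path, index=False)
        if progress:
            print(f"dataset {i + 1}/{cfg.n_sims} done", flush=True)

    df = pd.DataFrame(rows, columns=RAW_COLUMNS)
    return df.sort_values(["estimator", "p", "sim"], kind="stable").reset_index(drop=True)


def _mcse_modse(se2: np.ndarray, mod_se: float) -> float:
    # modSE = sqrt(mean(se^2)); delta method on the mean of se^2
    s = len(se2)
    return float(np.sqrt(np.var(se2, ddof=1) / s / (4.0 * mod_se**2))) if mod_se > 0 else np.nan


def performance(raw: pd.DataFrame, psi: float) -> pd.DataFrame:
    """Performance table, one row per estimator configuration."""
    out = []
    for (estimator, gen, p, r), grp in raw.groupby(
        ["estimator", "generalization", "p", "r"], sort=True
    ):
        ok = grp[(grp["status"] == "ok") & grp["estimate"].notna()]
        s = len(ok)
        n_flagged = len(grp) - s
        if s < 2:
            raise ValueError(
                f"need >= 2 complete rows for {estimator} (p={p}); got {s}"
            )
        est = ok["estimate"].to_numpy(dtype=float)
        se = ok["se"].to_numpy(dtype=float)
        lo = ok["ci_low"].to_numpy(dtype=float)
        hi = ok["ci_high"].to_numpy(dtype=float)

        bias = float(est.mean() - psi)
        emp_se = float(est.std(ddof=1))
        mod_se = float(np.sqrt(np.mean(se**2)))
        mod_se_arith = float(se.mean())
        mse = float(np.mean((est - psi) ** 2))
        cover = float(np.mean((lo <= psi) & (psi <= hi)))
        be_cover = float(np.mean((lo <= est.mean()) & (est.mean() <= hi)))

        if emp_se > 0:
            rel_err = float(100.0 * (mod_se / emp_se - 1.0))
            rel_err_mcse = float(
                100.0
                * (mod_se / emp_se)
                * np.sqrt(
                    np.var(se**2, ddof=1) / (4.0 * s * mod_se**4) + 1.0 / (2.0 * (s - 1))
                )
            )
        else:  # degenerate: constant estimates
            rel_err = np.nan
            rel_err_mcse = np.nan

        out.append(
            {
                "estimator": estimator,
                "generalization": gen,
                "p": p,
                "r": r,
                "n_sims_used": s,
                "n_flagged": n_flagged,
                "bias": bias,
                "bias_mcse": emp_se / np.sqrt(s),
                "empirical_se": emp_se,
                "empirical_se_mcse": emp_se / np.sqrt(2.0 * (s - 1)),
                "avg_model_se": mod_se,
                "avg_model_se_arith": mod_se_arith,
                "avg_model_se_mcse": _mcse_modse(se**2, mod_se),
                "relative_se_error_pct": rel_err,
                "relative_se_error_pct_mcse": rel_err_mcse,
                "mse": mse,
                "mse_mcse": float(
                    np.sqrt(np.sum(((est - psi) ** 2 - mse) ** 2) / (s * (s - 1)))
                ),
                "coverage": cover,
                "coverage_mcse": float(np.sqrt(cover * (1.0 - cover) / s)),
                "bias_eliminated_coverage": be_cover,
                "bias_eliminated_coverage_mcse": float(
                    np.sqrt(be_cover * (1.0 - be_cover) / s)
                ),
            }
        )
    return pd.DataFrame(out)


def zip_plot_data(raw: pd.DataFrame, psi: float) -> pd.DataFrame:
    """Per-dataset CI data ranked for zip plots.

    Rows are ordered, within each estimator configuration, by the centred
    standardised estimate |est - psi| / se; ``rank_pct`` is the fractional
    rank and ``covered`` flags whether the CI contains psi.
    """
    frames = []
    for key, grp in raw.groupby(["estimator", "generalization", "p", "r"], sort=True):
        ok = grp[(grp["status"] == "ok") & grp["estimate"].notna()].copy()
        z = (ok["estimate"] - psi).abs() / ok["se"]
        ok = ok.assign(z_abs=z).sort_values("z_abs", kind="stable")
        ok["rank_pct"] = (np.arange(len(ok)) + 1) / len(ok)
        ok["covered"] = (ok["ci_low"] <= psi) & (psi <= ok["ci_high"])
        frames.append(ok)
    return pd.concat(frames, ignore_index=True)
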