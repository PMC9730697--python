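"""Model-selection criteria, recovery metrics, and simulation-study drivers.

Two benchmark study designs are provided:

* **Study 1** (knot/degree selection): 3 density shapes x 10 (knots, degree)
  combinations with knots in 2..6 and degree in {3, 4}; N = 1000, J = 30.
* **Study 2** (estimator comparison): 3 Ramsay density shapes x
  N in {500, 1000, 2000} x J in {15, 30}; 6-knot degree-3 generating and
  fitting model, with both the Ramsay-curve fit and a fixed standard-normal
  density fit run on the same data.

Replications are seeded hierarchically (master seed -> condition -> rep), so
per-condition results are independent of execution order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grid_spline import Grid, build_basis, build_grid
from .saem_engine import SAEMConfig, run_saem
from .synthesis import gen_responses, make_true_world

__all__ = [
    "CriteriaResult",
    "RecoveryReport",
    "information_criteria",
    "count_parameters",
    "recovery_stats",
    "ise",
    "study1_conditions",
    "study2_conditions",
    "run_replication",
    "run_condition",
    "run_sim_study",
]

KNOT_DEGREE_GRID = [(k, d) for k in range(2, 7) for d in (3, 4)]
DENSITY_SHAPES = ("normal", "skewed", "bimodal")


@dataclass(frozen=True)
class CriteriaResult:
    logL: float
    n: int
    N: int
    aic: float
    bic: float
    hqic: float


@dataclass(frozen=True)
class RecoveryReport:
    bias: np.ndarray
    rmse: np.ndarray
    se: np.ndarray
    R: int


def information_criteria(logL: float, n: int, N: int,
                         aic_as_printed: bool = False) -> CriteriaResult:
    """AIC / BIC / HQIC from a marginal log-likelihood (natural logs).

    ``aic_as_printed`` switches AIC to the degenerate form -2logL + log(N),
    which carries no model-complexity penalty and is kept only for
    comparison; the default is the standard -2logL + 2n.
    """
    if n < 1:
        raise ValueError("parameter count must be >= 1")
    if N < 3:
        raise ValueError("need N >= 3 for log(log N)")
    d = -2.0 * logL
    aic = d + (math.log(N) if aic_as_printed else 2.0 * n)
    bic = d + n * math.log(N)
    hqic = d + 2.0 * n * math.log(math.log(N))
    return CriteriaResult(logL=logL, n=n, N=N, aic=aic, bic=bic, hqic=hqic)


def count_parameters(J: int, m: int, mode: str = "rc",
                     eta_constraint: bool = True) -> int:
    """Free-parameter count: 3 per item, plus the spline coefficients in
    ``rc`` mode (minus one by default: the basis spans the constant vector,
    so one coefficient is absorbed by the normalization)."""
    if J < 1:
        raise ValueError("J must be >= 1")
    if mode == "normal":
        return 3 * J
    if m < 1:
        raise ValueError("m must be >= 1 in rc mode")
    return 3 * J + (m - 1 if eta_constraint else m)


def recovery_stats(estimates: np.ndarray, truth: np.ndarray) -> RecoveryReport:
    """Bias, RMSE, and empirical SE of estimates across replications.

    ``estimates`` is R x P (replications by parameters); ``truth`` is either
    a length-P vector or an R x P matrix when the generating values differ
    per replication.
    """
    est = np.atleast_2d(np.asarray(estimates, float))
    if est.shape[0] < 1:
        raise ValueError("need at least one replication")
    err = est - np.asarray(truth, float)
    bias = err.mean(axis=0)
    rmse = np.sqrt((err**2).mean(axis=0))
    se = est.std(axis=0, ddof=1) if est.shape[0] > 1 else np.zeros(est.shape[1])
    return RecoveryReport(bias=bias, rmse=rmse, se=se, R=est.shape[0])


def ise(g_hat: np.ndarray, g_true: np.ndarray, grid: Grid) -> float:
    """Integrated squared error between two grid densities, times 1000.

    Mass vectors are converted to density heights (mass / step) and the
    squared difference is Riemann-summed, so the value does not depend on
    the grid resolution.
    """
    g_hat = np.asarray(g_hat, float)
    g_true = np.asarray(g_true, float)
    if g_hat.shape != (grid.Q,) or g_true.shape != (grid.Q,):
        raise ValueError("densities must live on the given grid")
    diff = (g_hat - g_true) / grid.step
    return 1000.0 * float(diff @ diff) * grid.step


def study1_conditions() -> list[dict]:
    """3 density shapes x 10 (knots, degree) combinations = 30 conditions."""
    return [
        {"study": 1, "shape": shape, "knots": k, "degree": d,
         "N": 1000, "J": 30}
        for shape in DENSITY_SHAPES for (k, d) in KNOT_DEGREE_GRID
    ]


def study2_conditions() -> list[dict]:
    """3 density shapes x 3 sample sizes x 2 test lengths = 18 conditions."""
    return [
        {"study": 2, "shape": shape, "knots": 6, "degree": 3, "N": N, "J": J}
        for shape in DENSITY_SHAPES for N in (500, 1000, 2000)
        for J in (15, 30)
    ]


def _child_seed(master: int, *path: int) -> int:
    """Deterministic sub-seed below 2^31 for (condition, replication) paths."""
    ss = np.random.SeedSequence([int(master), *map(int, path)])
    return int(ss.generate_state(1)[0] % (2**31 - 1))


def run_replication(shape: str, N: int, J: int, mode: str, seed: int,
                    knots: int = 6, degree: int = 3, study: int = 2,
                    max_iter: int = 2500, tol: float = 1e-4) -> dict:
    """Generate one data set and fit it; returns truth, estimates, and ISE."""
    grid = build_grid()
    basis = build_basis(grid, knots, degree)
    world = make_true_world(shape, N, J, basis, seed=seed, study=study)
    rng = np.random.default_rng(_child_seed(seed, 1))
    U = gen_responses(world.theta, world.items, rng)
    fit = run_saem(
        U, knots=knots, degree=degree,
        config=SAEMConfig(mode=mode, seed=_child_seed(seed, 2),
                          max_iter=max_iter, tol=tol),
    )
    g_hat = fit.density.g if mode == "rc" else np.asarray(fit.density)
    return {
        "true": world.items.as_array(),
        "est": fit.items.as_array(),
        "ise": ise(g_hat, world.density, grid),
        "criteria": fit.criteria,
        "logL": fit.marginal_loglik,
        "converged": fit.converged,
        "iterations": fit.iterations,
    }


def run_condition(shape: str, N: int, J: int, mode: str, reps: int,
                  master_seed: int, cond_index: int = 0, **kwargs) -> dict:
    """Run ``reps`` replications of one condition and aggregate recovery.

    Per-parameter-class summaries follow the usual reporting convention:
    bias averaged over items and replications; RMSE computed per item across
    replications, then averaged over items.
    """
    results = [
        run_replication(shape, N, J, mode,
                        seed=_child_seed(master_seed, cond_index, r), **kwargs)
        for r in range(reps)
    ]
    err = np.stack([res["est"] - res["true"] for res in results])  # (R, J, 3)
    summary = {}
    for p, name in enumerate(("a", "b", "c")):
        summary[f"bias_{name}"] = float(err[:, :, p].mean())
        summary[f"rmse_{name}"] = float(
            np.sqrt((err[:, :, p] ** 2).mean(axis=0)).mean())
    summary["ise"] = float(np.mean([res["ise"] for res in results]))
    for crit in ("aic", "bic", "hqic"):
        summary[crit] = float(np.mean([res["criteria"][crit]
                                       for res in results]))
    summary["converged_frac"] = float(np.mean([res["converged"]
                                               for res in results]))
    summary["mean_iterations"] = float(np.mean([res["iterations"]
                                                for res in results]))
    summary.update(shape=shape, N=N, J=J, mode=mode, reps=reps)
    return summary


def headline_recovery(mode: str, reps: int, master_seed: int,
                      shape: str = "skewed", N: int = 1000, J: int = 30
                      ) -> dict:
    """The benchmark intercept-recovery experiment: skewed 6-3 Ramsay truth,
    N = 1000, J = 30, full 2500-iteration budget."""
    return run_condition(shape, N, J, mode, reps=reps,
                         master_seed=master_seed)


def run_sim_study(study: int, replications: int = 100, seed: int = 0,
                  max_iter: int = 2500, tol: float = 1e-4,
                  conditions: list[dict] | None = None) -> pd.DataFrame:
    """Run a full study design and return one summary row per condition
    (study 2 fits each condition in both rc and normal mode)."""
    if study == 1:
        conds = conditions or study1_conditions()
        modes = ("rc",)
    elif study == 2:
        conds = conditions or study2_conditions()
        modes = ("rc", "normal")
    else:
        raise ValueError(f"study must be 1 or 2, got {study}")
    rows = []
    for ci, cond in enumerate(conds):
        for mode in modes:
            row = run_condition(
                cond["shape"], cond["N"], cond["J"], mode,
                reps=replications, master_seed=seed, cond_index=ci,
                knots=cond["knots"], degree=cond["degree"],
                study=cond["study"], max_iter=max_iter, tol=tol)
            row.update(knots=cond["knots"], degree=cond["degree"])
            rows.append(row)
    return pd.DataFrame(rows)
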