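"""Monte Carlo evaluation of the cutpoint methods.

``run_scenario`` simulates ``n_sim`` independent datasets from one scenario
and applies a subset of the methods to each, producing a long-format estimate
table (one row per scenario x replicate x method, missing estimates flagged,
never dropped).  ``compute_performance``/``aggregate_performance`` turn
estimate tables into the performance measures

* bias       = mean(theta_hat) - theta
* EmpSE      = sqrt( sum (theta_hat - mean)^2 / (n-1) )
* MSE        = mean (theta_hat - theta)^2
* precision gain of M vs reference R = 100 * ((EmpSE_R / EmpSE_M)^2 - 1)

each with its Monte Carlo standard error: MCSE(bias) = EmpSE/sqrt(n),
MCSE(EmpSE) = EmpSE/sqrt(2(n-1)), MCSE(MSE) from the squared-error spread,
and a leave-one-replicate-out jackknife for the precision gain.
"""
from __future__ import annotations

import math
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from joblib import Parallel, delayed

from .cutpoints import METHODS, EstimateSettings, estimate_all
from .simulate import CensoringCalibration, Scenario, calibrate_censoring, simulate_dataset

__all__ = [
    "SCENARIO_FACTORS",
    "run_scenario",
    "run_study",
    "compute_performance",
    "aggregate_performance",
    "required_nsim",
]

SCENARIO_FACTORS = ("distribution", "theta", "n_obs", "pc_t", "pc_f")


def _one_replicate(scenario: Scenario, rep_seed: int, methods, settings,
                   calibration: CensoringCalibration) -> list[dict]:
    data = simulate_dataset(scenario, seed=rep_seed, calibration=calibration)
    results = estimate_all(data, methods=methods, settings=settings, seed=rep_seed)
    rows = []
    for res in results:
        rows.append({
            "method": res.method,
            "cutpoint": res.cutpoint if not res.failed else np.nan,
            "missing": bool(res.failed),
            "criterion_value": res.criterion_value,
        })
    return rows


def run_scenario(
    scenario: Scenario,
    n_sim: int,
    methods: Sequence[str] = METHODS,
    settings: EstimateSettings | None = None,
    workers: int = 1,
) -> pd.DataFrame:
    """Estimate table for one scenario: n_sim replicates of every method.

    Replicate seeds derive deterministically from the scenario seed; results
    are identical for any ``workers`` value.  Re-running a single replicate
    through :func:`survcut.simulate.simulate_dataset` and
    :func:`survcut.cutpoints.estimate_all` with its recorded seed reproduces
    its estimate exactly.
    """
    if n_sim < 2:
        raise ValueError("n_sim must be at least 2")
    settings = settings or EstimateSettings()
    rep_seeds = [
        int(s) & 0x7FFFFFFF
        for s in np.random.SeedSequence(scenario.seed).generate_state(n_sim)
    ]
    calibration = calibrate_censoring(scenario)
    if workers == 1:
        per_rep = [_one_replicate(scenario, s, methods, settings, calibration)
                   for s in rep_seeds]
    else:
        per_rep = Parallel(n_jobs=workers)(
            delayed(_one_replicate)(scenario, s, methods, settings, calibration)
            for s in rep_seeds)
    rows = []
    for rep, (seed, rep_rows) in enumerate(zip(rep_seeds, per_rep)):
        for row in rep_rows:
            rows.append({
                "distribution": scenario.distribution,
                "theta": scenario.theta,
                "n_obs": scenario.n_obs,
                "pc_t": scenario.pc_t,
                "pc_f": scenario.pc_f,
                "scenario_seed": scenario.seed,
                "replicate": rep,
                "seed": seed,
                **row,
            })
    return pd.DataFrame(rows)


def run_study(
    scenarios: Sequence[Scenario],
    n_sim: int,
    methods: Sequence[str] = METHODS,
    settings: EstimateSettings | None = None,
    workers: int = 1,
    progress: bool = False,
) -> pd.DataFrame:
    """Concatenated estimate tables over a scenario collection."""
    tables = []
    for i, sc in enumerate(scenarios):
        if progress:
            print(f"[survcut] scenario {i + 1}/{len(scenarios)}: {sc.distribution}, "
                  f"theta={sc.theta}, n={sc.n_obs}, pc_t={sc.pc_t}, pc_f={sc.pc_f}",
                  flush=True)
        tables.append(run_scenario(sc, n_sim, methods, settings, workers))
    return pd.concat(tables, ignore_index=True)


def required_nsim(sd: float, target_mcse: float) -> int:
    """Replications needed so MCSE(bias) = sd/sqrt(n) falls below the target:
    ceil((sd / target_mcse)^2)."""
    if sd <= 0 or target_mcse <= 0:
        raise ValueError("sd and target_mcse must be positive")
    return math.ceil((sd / target_mcse) ** 2)


# ---------------------------------------------------------------------------
# performance measures
# ---------------------------------------------------------------------------

def _performance_row(est: np.ndarray, theta: float) -> dict:
    n = est.size
    mean = est.mean()
    bias = mean - theta
    emp_se = float(np.sqrt(np.sum((est - mean) ** 2) / (n - 1)))
    sq_err = (est - theta) ** 2
    mse = float(sq_err.mean())
    mse_mcse = float(np.sqrt(np.sum((sq_err - mse) ** 2) / (n * (n - 1))))
    return {
        "bias": float(bias),
        "bias_mcse": emp_se / math.sqrt(n),
        "emp_se": emp_se,
        "emp_se_mcse": emp_se / math.sqrt(2.0 * (n - 1)),
        "mse": mse,
        "mse_mcse": mse_mcse,
        "n_used": int(n),
    }


def _gain(emp_se_ref: float, emp_se: float) -> float:
    return 100.0 * ((emp_se_ref / emp_se) ** 2 - 1.0)


def _jackknife_gain_mcse(est_m: np.ndarray, est_r: np.ndarray) -> float:
    """Leave-one-replicate-out jackknife SE of the precision gain.

    Estimates are paired by replicate; pairs with a missing value on either
    side are excluded before the jackknife.
    """
    n = est_m.size
    if n < 3 or est_m.size != est_r.size:
        return float("nan")
    gains = np.empty(n)
    idx = np.arange(n)
    for i in range(n):
        keep = idx != i
        se_m = np.std(est_m[keep], ddof=1)
        se_r = np.std(est_r[keep], ddof=1)
        gains[i] = _gain(se_r, se_m) if se_m > 0 else np.nan
    if np.isnan(gains).any():
        return float("nan")
    return float(np.sqrt((n - 1) / n * np.sum((gains - gains.mean()) ** 2)))


def compute_performance(
    estimates: pd.DataFrame,
    theta: float | None = None,
    reference_method: str = "E1",
    by: Sequence[str] = SCENARIO_FACTORS,
) -> pd.DataFrame:
    """Performance table per (group, method) from a long estimate table.

    ``estimates`` must carry columns ``method`` and ``cutpoint`` (NaN when
    missing) plus the grouping columns.  ``theta`` defaults to the table's
    ``theta`` column, which must be constant within each group — pooling
    bias across different true cutpoints is disallowed.
    """
    by = [c for c in by if c in estimates.columns]
    if theta is None and "theta" not in estimates.columns:
        raise ValueError("theta not given and no 'theta' column present")
    rows = []
    grouped = estimates.groupby(by, sort=True) if by else [((), estimates)]
    for key, grp in grouped:
        if theta is None:
            thetas = grp["theta"].unique()
            if len(thetas) != 1:
                raise ValueError(
                    "cannot pool bias across different true cutpoints; "
                    "group by 'theta' or pass an explicit theta")
            th = float(thetas[0])
        else:
            th = float(theta)
        ref = grp[grp["method"] == reference_method]
        if ref.empty:
            raise ValueError(f"reference method {reference_method!r} absent")
        ref_by_rep = ref.set_index(["scenario_seed", "replicate"])["cutpoint"] \
            if {"scenario_seed", "replicate"}.issubset(grp.columns) else None
        ref_vals = ref["cutpoint"].dropna().to_numpy()
        ref_se = float(np.std(ref_vals, ddof=1)) if ref_vals.size >= 2 else np.nan
        for method, sub in grp.groupby("method", sort=True):
            est = sub["cutpoint"].dropna().to_numpy()
            n_missing = int(sub["cutpoint"].isna().sum())
            if est.size < 2:
                raise ValueError(f"method {method!r} has fewer than two estimates")
            row = dict(zip(by, key if isinstance(key, tuple) else (key,)))
            row["method"] = method
            row.update(_performance_row(est, th))
            row["n_missing"] = n_missing
            if method == reference_method:
                row["precision_gain_vs_ref"] = 0.0
                row["precision_gain_mcse"] = 0.0
            elif ref_by_rep is not None:
                pair = sub.set_index(["scenario_seed", "replicate"])["cutpoint"]
                joined = pd.concat({"m": pair, "r": ref_by_rep}, axis=1).dropna()
                se_m = float(np.std(joined["m"], ddof=1))
                row["precision_gain_vs_ref"] = (
                    _gain(float(np.std(joined["r"], ddof=1)), se_m)
                    if se_m > 0 else np.nan)
                row["precision_gain_mcse"] = _jackknife_gain_mcse(
                    joined["m"].to_numpy(), joined["r"].to_numpy())
            else:
                se_m = float(np.std(est, ddof=1))
                row["precision_gain_vs_ref"] = (
                    _gain(ref_se, se_m) if se_m > 0 else np.nan)
                row["precision_gain_mcse"] = float("nan")
            rows.append(row)
    return pd.DataFrame(rows)


def aggregate_performance(
    estimates: pd.DataFrame,
    by: Sequence[str],
    reference_method: str = "E1",
) -> pd.DataFrame:
    """Recompute the performance measures after pooling replicate-level
    estimates across the scenario factors not listed in ``by``.

    Pooling across different true cutpoints is refused (the bias would mix
    targets); include ``"theta"`` in ``by``.  The returned table records the
    pooled factors.
    """
    by = list(by)
    if "theta" not in by and estimates["theta"].nunique() > 1:
        raise ValueError("cannot pool across different theta; include 'theta' in by")
    pooled_over = [f for f in SCENARIO_FACTORS if f not in by]
    table = compute_performance(estimates, reference_method=reference_method, by=by)
    table.attrs["pooled_factors"] = pooled_over
    return table
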