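"""Rendering of study outputs: tidy CSV tables and the two plot types
(bias boxplots by true cutpoint; a nested-loop plot over all scenarios).

The plotting layer never recomputes measures — every rendered number comes
from the performance table it is given.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .mcstudy import SCENARIO_FACTORS, aggregate_performance

__all__ = ["PlotSpec", "make_table", "write_table", "nested_loop_plot",
           "bias_boxplot"]


def write_table(table: pd.DataFrame, path: str | Path) -> Path:
    """Write a table as CSV with shortest-round-trip floats, so reading it
    back reproduces every numeric value exactly."""
    path = Path(path)
    table.to_csv(path, index=False, float_format=lambda v: repr(float(v)))
    return path

_MEASURES = ("bias", "emp_se", "mse", "precision_gain_vs_ref")

_LAYOUTS = {
    "by_theta": ("theta",),
    "by_theta_n_pct": ("theta", "n_obs", "pc_t"),
    "by_full_scenario": SCENARIO_FACTORS,
}


@dataclass(frozen=True)
class PlotSpec:
    """Layout for one rendered figure."""

    kind: str  # "bias_boxplot" | "nested_loop"
    factor_order: tuple[str, ...] = ("distribution", "theta", "n_obs", "pc_t", "pc_f")
    methods: tuple[str, ...] | None = None
    path: str | Path = "plot.png"

    def __post_init__(self) -> None:
        if self.kind not in ("bias_boxplot", "nested_loop"):
            raise ValueError(f"unknown plot kind {self.kind!r}")
        if sorted(self.factor_order) != sorted(SCENARIO_FACTORS):
            raise ValueError("factor_order must be a permutation of the scenario factors")


def make_table(performance: pd.DataFrame, layout: str = "by_theta") -> pd.DataFrame:
    """Wide table per layout: one row per (measure, group), one column pair
    (value, MCSE) per method, with the minimum-|bias| method marked."""
    if performance.empty:
        raise ValueError("performance table is empty")
    if layout not in _LAYOUTS:
        raise ValueError(f"unknown layout {layout!r}; pick from {sorted(_LAYOUTS)}")
    keys = [k for k in _LAYOUTS[layout] if k in performance.columns]
    if not keys:
        raise ValueError(f"layout {layout!r} needs columns {_LAYOUTS[layout]}")
    rows = []
    for gkey, grp in performance.groupby(keys, sort=True):
        gkey = gkey if isinstance(gkey, tuple) else (gkey,)
        by_method = grp.set_index("method")
        best = by_method["bias"].abs().idxmin()
        for measure in _MEASURES:
            mcse_col = {"precision_gain_vs_ref": "precision_gain_mcse"}.get(
                measure, f"{measure}_mcse")
            row = dict(zip(keys, gkey))
            row["measure"] = measure
            for method in by_method.index:
                row[method] = by_method.loc[method, measure]
                row[f"{method}_mcse"] = by_method.loc[method, mcse_col]
            row["min_abs_bias_method"] = best
            rows.append(row)
    return pd.DataFrame(rows)


def _scenario_order(perf: pd.DataFrame, factor_order: Sequence[str]) -> pd.DataFrame:
    cols = [c for c in factor_order if c in perf.columns]
    return perf.sort_values([*cols, "method"], kind="stable").reset_index(drop=True)


def nested_loop_plot(performance: pd.DataFrame, spec: PlotSpec) -> Path:
    """Bias of every scenario on one axis, scenarios ordered by nested factor
    loops (outermost factor first), with step lines tracing the factor levels
    below the curves.  Deterministic for fixed inputs."""
    missing = [f for f in spec.factor_order if f not in performance.columns]
    if missing:
        raise ValueError(f"performance table lacks scenario factors {missing}")
    perf = _scenario_order(performance, spec.factor_order)
    methods = list(spec.methods) if spec.methods else sorted(perf["method"].unique())
    scen = perf[list(spec.factor_order)].drop_duplicates().reset_index(drop=True)
    n_scen = len(scen)
    pos = {tuple(row): i for i, row in enumerate(scen.itertuples(index=False))}

    fig, (ax, ax_f) = plt.subplots(
        2, 1, figsize=(max(8.0, n_scen / 12.0), 7.0), sharex=True,
        gridspec_kw={"height_ratios": [3, 1.6]})
    for method in methods:
        sub = perf[perf["method"] == method]
        xs = [pos[tuple(r)] for r in sub[list(spec.factor_order)].itertuples(index=False)]
        order = np.argsort(xs)
        ax.plot(np.asarray(xs)[order], sub["bias"].to_numpy()[order],
                drawstyle="steps-mid", label=method, linewidth=1.0)
    ax.axhline(0.0, color="grey", linewidth=0.6)
    ax.set_ylabel("bias")
    ax.legend(loc="best", fontsize=8, ncol=min(len(methods), 5))
    # factor-level step traces
    for row_i, factor in enumerate(spec.factor_order):
        levels = sorted(scen[factor].unique())
        coded = scen[factor].map({v: i for i, v in enumerate(levels)})
        frac = coded / max(len(levels) - 1, 1)
        ax_f.plot(np.arange(n_scen), -row_i + 0.8 * frac,
                  drawstyle="steps-mid", linewidth=0.8)
        ax_f.text(-0.01 * max(n_scen, 1), -row_i + 0.4,
                  f"{factor}: {levels}", ha="right", va="center", fontsize=7)
    ax_f.set_yticks([])
    ax_f.set_xlabel("scenario")
    fig.tight_layout()
    out = Path(spec.path)
    fig.savefig(out, dpi=150)
    plt.close(fig)
    return out


def bias_boxplot(
    estimates: pd.DataFrame,
    theta_levels: Sequence[float],
    path: str | Path = "bias_boxplot.png",
    methods: Sequence[str] | None = None,
) -> Path:
    """Per-method boxes of the error (theta_hat - theta) grouped by the true
    cutpoint, outliers suppressed.  Methods with no estimates in a group are
    omitted with a warning."""
    theta_levels = list(theta_levels)
    present = set(estimates["theta"].unique())
    missing_levels = [t for t in theta_levels if t not in present]
    if missing_levels:
        raise ValueError(f"no estimates for theta levels {missing_levels}")
    methods = list(methods) if methods else sorted(estimates["method"].unique())

    fig, axes = plt.subplots(1, len(theta_levels),
                             figsize=(3.2 * len(theta_levels), 4.2), sharey=False)
    axes = np.atleast_1d(axes)
    for ax, theta in zip(axes, theta_levels):
        grp = estimates[estimates["theta"] == theta]
        data, labels = [], []
        for method in methods:
            vals = grp.loc[grp["method"] == method, "cutpoint"].dropna().to_numpy()
            if vals.size == 0:
                print(f"[survcut] warning: method {method} has no estimates "
                      f"at theta={theta}; omitted", flush=True)
                continue
            data.append(vals - theta)
            labels.append(method)
        if not data:
            raise ValueError(f"no estimates at theta={theta}")
        ax.boxplot(data, tick_labels=labels, showfliers=False)
        ax.axhline(0.0, color="grey", linewidth=0.6)
        ax.set_title(f"theta = {theta}")
        ax.set_ylabel("bias")
    fig.tight_layout()
    out = Path(path)
    fig.savefig(out, dpi=150)
    plt.close(fig)
    return out
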