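"""Synthetic survival data with a dichotomised biomarker effect.

Subjects carry a continuous biomarker X and covariates Z1 (binary), Z2, Z3
(continuous).  The hazard is h0(t) * exp(beta_X * 1{X > theta} + beta' Z): the
biomarker acts on survival only through the dichotomisation at the true
cutpoint theta.  Event times come from an exponential, Weibull or Gompertz
baseline by inverse-transform sampling; follow-up is administratively
truncated at t = 1 and an independent uniform drop-out process censors a
calibrated share of subjects earlier.  Two targets control censoring:

* ``pc_t`` — total proportion censored,
* ``pc_f`` — share of the censorings that occur strictly before t = 1.

Both are met by calibrating (i) a multiplier on the baseline rate and (ii) a
per-subject drop-out probability on a large common-random-numbers sample.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import product
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .datasets import SurvivalDataset

__all__ = [
    "DISTRIBUTIONS",
    "DEFAULT_DIST_PARAMS",
    "DEFAULT_BETAS",
    "DEFAULT_FACTOR_LEVELS",
    "Scenario",
    "CensoringCalibration",
    "build_scenario_grid",
    "draw_covariates",
    "linear_predictor",
    "inverse_transform_time",
    "true_survival",
    "calibrate_censoring",
    "simulate_dataset",
]

DISTRIBUTIONS = ("exponential", "weibull", "gompertz")

#: Baseline-hazard parameters before censoring calibration rescales the rate.
DEFAULT_DIST_PARAMS: dict[str, dict[str, float]] = {
    "exponential": {"rate": 0.2},
    "weibull": {"shape": 1.5, "rate": 0.1},
    "gompertz": {"a": 0.003, "b": 0.098},
}

#: (beta_X, beta_Z1, beta_Z2, beta_Z3): hazard ratios 3, 2, 0.5, 2.
DEFAULT_BETAS = (math.log(3.0), math.log(2.0), math.log(0.5), math.log(2.0))

#: Factor levels of the full study design (3*3*3*3*2 = 162 scenarios).
DEFAULT_FACTOR_LEVELS: dict[str, tuple] = {
    "distributions": DISTRIBUTIONS,
    "theta": (0.2, 0.7, 1.2),
    "n_obs": (250, 500, 750),
    "pc_t": (0.2, 0.5, 0.8),
    "pc_f": (0.25, 0.50),
}

_COVARIATE_COLS = ("Z1", "Z2", "Z3")


def _params_tuple(distribution: str, params: Mapping[str, float] | None) -> tuple:
    base = dict(DEFAULT_DIST_PARAMS[distribution])
    if params:
        unknown = set(params) - set(base)
        if unknown:
            raise ValueError(f"unknown {distribution} parameters {sorted(unknown)}")
        base.update(params)
    return tuple(sorted(base.items()))


@dataclass(frozen=True)
class Scenario:
    """One generative configuration of the simulation study."""

    distribution: str
    theta: float
    n_obs: int
    pc_t: float
    pc_f: float
    dist_params: Mapping[str, float] | None = None
    betas: tuple[float, float, float, float] = DEFAULT_BETAS
    seed: int = 0

    def __post_init__(self) -> None:
        if self.distribution not in DISTRIBUTIONS:
            raise ValueError(f"unknown distribution {self.distribution!r}")
        object.__setattr__(
            self, "dist_params", _params_tuple(self.distribution, self.dist_params)
        )
        object.__setattr__(self, "betas", tuple(float(b) for b in self.betas))
        if len(self.betas) != 4:
            raise ValueError("betas must have four entries (beta_X, beta_Z1..Z3)")
        if self.n_obs < 2:
            raise ValueError("n_obs must be at least 2")
        if not (0.0 < self.pc_t < 1.0 and 0.0 < self.pc_f < 1.0):
            raise ValueError("pc_t and pc_f must lie strictly in (0, 1)")
        if not math.isfinite(self.theta):
            raise ValueError("theta must be finite")
        if any(v <= 0 for _, v in self.dist_params):
            raise ValueError("distribution parameters must be strictly positive")

    @property
    def params(self) -> dict[str, float]:
        return dict(self.dist_params)

    @property
    def calibration_key(self) -> tuple:
        """Scenario fields the censoring calibration depends on (not n_obs/seed)."""
        return (self.distribution, self.dist_params, self.theta, self.betas,
                self.pc_t, self.pc_f)


def build_scenario_grid(config: Mapping | None = None, master_seed: int | None = None) -> list[Scenario]:
    """Cartesian product of factor levels, with deterministic child seeds.

    ``config`` maps ``distributions, theta, n_obs, pc_t, pc_f`` to level
    sequences (defaults: the full 162-scenario design) and may carry ``betas``,
    ``dist_params`` and ``master_seed``.  Order is stable: distribution
    outermost, then theta, n_obs, pc_t, pc_f innermost.
    """
    cfg = dict(config) if config else {}
    if master_seed is None:
        master_seed = int(cfg.pop("master_seed", 0))
    levels = {}
    for key in DEFAULT_FACTOR_LEVELS:
        vals = tuple(cfg.get(key, DEFAULT_FACTOR_LEVELS[key]))
        if len(vals) == 0:
            raise ValueError(f"factor {key!r} has no levels")
        if len(set(vals)) != len(vals):
            raise ValueError(f"factor {key!r} has duplicate levels")
        levels[key] = vals
    betas = tuple(cfg.get("betas", DEFAULT_BETAS))
    dist_params = cfg.get("dist_params", {})

    combos = list(product(levels["distributions"], levels["theta"], levels["n_obs"],
                          levels["pc_t"], levels["pc_f"]))
    # Counter-based child seeds: reproducible independently and in parallel.
    child = np.random.SeedSequence(master_seed).generate_state(len(combos))
    return [
        Scenario(distribution=d, theta=t, n_obs=int(n), pc_t=pt, pc_f=pf,
                 dist_params=dist_params.get(d), betas=betas,
                 seed=int(s) & 0x7FFFFFFF)
        for (d, t, n, pt, pf), s in zip(combos, child)
    ]


# ---------------------------------------------------------------------------
# covariates and hazard structure
# ---------------------------------------------------------------------------

def draw_covariates(n: int, seed: int | np.random.Generator = 0) -> pd.DataFrame:
    """Draw n subjects: X, Z2, Z3 ~ N(0,1); Z1 ~ Bernoulli(0.5)."""
    if n < 1:
        raise ValueError("n must be at least 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return pd.DataFrame({
        "X": rng.standard_normal(n),
        "Z1": rng.integers(0, 2, size=n).astype(float),
        "Z2": rng.standard_normal(n),
        "Z3": rng.standard_normal(n),
    })


def linear_predictor(
    covariates: pd.DataFrame, theta: float, betas: Sequence[float] = DEFAULT_BETAS
) -> np.ndarray:
    """beta_X * 1{X > theta} + beta_Z1*Z1 + beta_Z2*Z2 + beta_Z3*Z3 per subject.

    The boundary value X == theta belongs to the low-risk group.
    """
    betas = np.asarray(betas, dtype=float)
    if betas.shape != (4,):
        raise ValueError("betas must have four entries")
    xd = (covariates["X"].to_numpy(dtype=float) > theta).astype(float)
    z = covariates[list(_COVARIATE_COLS)].to_numpy(dtype=float)
    return betas[0] * xd + z @ betas[1:]


# ---------------------------------------------------------------------------
# event-time generation and its closed-form inverse
# ---------------------------------------------------------------------------

def _check_params(distribution: str, params: Mapping[str, float]) -> dict[str, float]:
    if distribution not in DISTRIBUTIONS:
        raise ValueError(f"unknown distribution {distribution!r}")
    p = {k: float(v) for k, v in dict(params).items()}
    expected = set(DEFAULT_DIST_PARAMS[distribution])
    if set(p) != expected:
        raise ValueError(f"{distribution} needs parameters {sorted(expected)}")
    if any(v <= 0 for v in p.values()):
        raise ValueError("distribution parameters must be strictly positive")
    return p


def inverse_transform_time(u, lp, distribution: str, params: Mapping[str, float]):
    """Event time with survival probability u under hazard h0(t)*exp(lp).

    Closed forms: exponential T = -log(u)/(rate*e^lp); Weibull
    T = (-log(u)/(rate*e^lp))^(1/shape); Gompertz
    T = (1/b)*log(1 - b*log(u)/(a*e^lp)).  Monotone decreasing in u.
    """
    p = _check_params(distribution, params)
    u = np.asarray(u, dtype=float)
    if np.any(u <= 0.0) or np.any(u >= 1.0):
        raise ValueError("u must lie strictly in (0, 1)")
    scale = np.exp(np.asarray(lp, dtype=float))
    neg_log_u = -np.log(u)
    if distribution == "exponential":
        return neg_log_u / (p["rate"] * scale)
    if distribution == "weibull":
        return (neg_log_u / (p["rate"] * scale)) ** (1.0 / p["shape"])
    return np.log1p(p["b"] * neg_log_u / (p["a"] * scale)) / p["b"]


def true_survival(t, lp, distribution: str, params: Mapping[str, float]):
    """Closed-form S(t) under hazard h0(t)*exp(lp) (inverse of the sampler)."""
    p = _check_params(distribution, params)
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be non-negative")
    scale = np.exp(np.asarray(lp, dtype=float))
    if distribution == "exponential":
        return np.exp(-p["rate"] * scale * t)
    if distribution == "weibull":
        return np.exp(-p["rate"] * scale * t ** p["shape"])
    return np.exp(-(p["a"] / p["b"]) * scale * np.expm1(p["b"] * t))


def _scaled_params(distribution: str, params: Mapping[str, float], multiplier: float) -> dict:
    p = dict(params)
    key = "a" if distribution == "gompertz" else "rate"
    p[key] = p[key] * multiplier
    return p


# ---------------------------------------------------------------------------
# censoring calibration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CensoringCalibration:
    """Baseline-rate multiplier and drop-out probability hitting (pc_t, pc_f)."""

    multiplier: float
    dropout_prob: float
    realized_pc_t: float
    realized_pc_f: float
    converged: bool
    n_cal: int
    tol: float


_CALIBRATION_CACHE: dict[tuple, CensoringCalibration] = {}

#: Fixed seed of the calibration sample; calibration is a deterministic
#: function of the scenario, shared across replicates.
CALIBRATION_SEED = 190_753


def _censoring_draws(n_cal: int, seed: int, theta: float, betas, rng=None):
    rng = np.random.default_rng(seed)
    cov = draw_covariates(n_cal, rng)
    lp = linear_predictor(cov, theta, betas)
    tiny = np.finfo(float).tiny
    u = np.clip(rng.random(n_cal), tiny, 1.0 - 1e-16)
    v = rng.random(n_cal)
    w = np.clip(rng.random(n_cal), tiny, None)  # drop-out times C ~ U[0,1]
    return lp, u, v, w


def calibrate_censoring(
    scenario: Scenario,
    n_cal: int = 100_000,
    tol: float = 0.02,
    seed: int = CALIBRATION_SEED,
) -> CensoringCalibration:
    """Solve for (rate multiplier, drop-out probability) meeting (pc_t, pc_f).

    On a common-random-numbers calibration sample the realized total censoring
    proportion is monotone decreasing in the rate multiplier and the realized
    early share is monotone increasing in the drop-out probability q, so the
    two targets are met by nested Brent root-finding: for each trial q the
    multiplier is solved to hit pc_t, then q is solved to hit pc_f.
    Results are cached per scenario (independent of n_obs and seed).
    """
    if n_cal < 10_000:
        raise ValueError("n_cal must be at least 10_000")
    key = (scenario.calibration_key, n_cal, tol, seed)
    hit = _CALIBRATION_CACHE.get(key)
    if hit is not None:
        return hit

    dist, params = scenario.distribution, scenario.params
    pc_t, pc_f = scenario.pc_t, scenario.pc_f
    lp, u, v, w = _censoring_draws(n_cal, seed, scenario.theta, scenario.betas)

    def realized(multiplier: float, q: float) -> tuple[float, float]:
        t_event = inverse_transform_time(
            u, lp, dist, _scaled_params(dist, params, multiplier))
        drop = v < q
        censor_time = np.where(drop, np.minimum(w, 1.0), 1.0)
        cens = t_event > censor_time
        pct = cens.mean()
        n_cens = cens.sum()
        pcf = float((cens & drop).sum() / n_cens) if n_cens else 0.0
        return float(pct), pcf

    def pct_gap(log_m: float, q: float) -> float:
        return realized(10.0 ** log_m, q)[0] - pc_t

    def solve_multiplier(q: float) -> float:
        lo, hi = -8.0, 8.0
        return 10.0 ** brentq(pct_gap, lo, hi, args=(q,), xtol=1e-8, maxiter=200)

    converged = True
    try:
        def pcf_gap(q: float) -> float:
            return realized(solve_multiplier(q), q)[1] - pc_f

        q_star = brentq(pcf_gap, 0.0, 1.0, xtol=1e-7, maxiter=200)
        m_star = solve_multiplier(q_star)
    except (ValueError, RuntimeError):
        converged = False
        q_star, m_star = float("nan"), float("nan")

    if converged:
        pct, pcf = realized(m_star, q_star)
        converged = abs(pct - pc_t) <= tol and abs(pcf - pc_f) <= tol
    else:
        pct, pcf = float("nan"), float("nan")

    cal = CensoringCalibration(m_star, q_star, pct, pcf, converged, n_cal, tol)
    _CALIBRATION_CACHE[key] = cal
    return cal


# ---------------------------------------------------------------------------
# dataset generation
# ---------------------------------------------------------------------------

def simulate_dataset(
    scenario: Scenario,
    seed: int | None = None,
    calibration: CensoringCalibration | None = None,
) -> SurvivalDataset:
    """One simulated dataset: columns time, event, X, Z1, Z2, Z3.

    Follow-up is T = min(T_S, C, 1) with event = 1 iff the event time T_S
    occurs no later than drop-out and end of follow-up.  Reproducible under
    ``seed`` (default: the scenario seed).
    """
    if calibration is None:
        calibration = calibrate_censoring(scenario)
    if not calibration.converged:
        raise RuntimeError(
            f"censoring calibration did not converge for {scenario!r}")
    if seed is None:
        seed = scenario.seed
    rng = np.random.default_rng(seed)
    n = scenario.n_obs
    cov = draw_covariates(n, rng)
    lp = linear_predictor(cov, scenario.theta, scenario.betas)
    tiny = np.finfo(float).tiny
    u = np.clip(rng.random(n), tiny, 1.0 - 1e-16)
    v = rng.random(n)
    w = np.clip(rng.random(n), tiny, None)

    params = _scaled_params(scenario.distribution, scenario.params,
                            calibration.multiplier)
    t_event = inverse_transform_time(u, lp, scenario.distribution, params)
    drop = v < calibration.dropout_prob
    censor_time = np.where(drop, np.minimum(w, 1.0), 1.0)
    time = np.minimum(t_event, censor_time)
    event = (t_event <= censor_time).astype(int)

    frame = cov.copy()
    frame.insert(0, "event", event)
    frame.insert(0, "time", time)
    return SurvivalDataset(frame)
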