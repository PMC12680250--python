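"""The nine cutpoint-estimation methods.

All methods search dichotomisations X_D = 1{X > c} of the biomarker inside a
candidate grid bounded so that each group keeps at least ``min_prop`` of the
subjects.  The multivariable methods refit the Cox model (X_D plus the
covariates) at every candidate and rank the fits by one criterion:

====== ==============================================================
A      largest model LRT chi-square; HR and p by twofold cross-validation
B      largest chi-square on a random half; HR and p from the other half
C1/C2  largest Harrell c-index (exhaustive scan / genetic algorithm)
D1/D2  largest Gonen-Heller CPE (exhaustive scan / genetic algorithm)
E1     smallest AIC with X_D as covariate
E2     smallest AIC with X_D as a stratum (covariates only as regressors)
F      smallest log-rank p over univariable dichotomisations
====== ==============================================================

A and E1 are analytically identical (argmax of 2*(logPL - logPL0) equals
argmin of -2*logPL + 2k when k and logPL0 do not vary over the grid); the
package computes both routes independently.  Criterion ties break toward the
smallest candidate.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .cox import (ConcordancePairs, PartialLikelihood, _newton, fit_cox,
                  gonen_heller_cpe, logrank_test)
from .datasets import SurvivalDataset

__all__ = [
    "METHODS",
    "CandidateGrid",
    "CutpointResult",
    "GASettings",
    "EstimateSettings",
    "candidate_grid",
    "dichotomise",
    "estimate_maxchi2",
    "crossval_effect",
    "estimate_splitsample",
    "estimate_concordance_addfor",
    "estimate_concordance_genetic",
    "estimate_minaic",
    "estimate_minp_logrank",
    "estimate_all",
]

METHODS = ("A", "B", "C1", "C2", "D1", "D2", "E1", "E2", "F")


@dataclass(frozen=True)
class CandidateGrid:
    """Sorted distinct candidate cutpoints with their group-size bound."""

    values: np.ndarray
    min_prop: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.values.size == 0:
            raise ValueError("candidate grid is empty")
        if np.any(np.diff(self.values) <= 0):
            raise ValueError("candidate values must be strictly increasing")

    @property
    def bounds(self) -> tuple[float, float]:
        return float(self.values[0]), float(self.values[-1])

    def __len__(self) -> int:
        return self.values.size


def candidate_grid(x, min_prop: float = 0.10) -> CandidateGrid:
    """Distinct observed values v with min_prop <= P(X <= v) <= 1 - min_prop."""
    x = np.asarray(x, dtype=float)
    if not (0.0 < min_prop < 0.5):
        raise ValueError("min_prop must lie in (0, 0.5)")
    values = np.unique(x)
    if values.size < 2:
        raise ValueError("biomarker is constant")
    if values.size < 10:
        raise ValueError("need at least 10 distinct biomarker values")
    xs = np.sort(x)
    prop_low = np.searchsorted(xs, values, side="right") / x.size
    eps = 1e-12
    keep = (prop_low >= min_prop - eps) & (prop_low <= 1.0 - min_prop + eps)
    if not keep.any():
        raise ValueError("no feasible candidate under min_prop")
    return CandidateGrid(values[keep], min_prop)


def dichotomise(x, cutpoint: float) -> np.ndarray:
    """0 where x <= cutpoint, 1 where x > cutpoint."""
    if not np.isfinite(cutpoint):
        raise ValueError("cutpoint must be finite")
    return (np.asarray(x, dtype=float) > cutpoint).astype(float)


@dataclass(frozen=True)
class CutpointResult:
    """One method's estimate, or a flagged failure."""

    method: str
    cutpoint: float
    criterion_name: str
    criterion_value: float
    hazard_ratio: float | None = None
    p_value: float | None = None
    failed: bool = False
    diagnostics: dict = field(default_factory=dict)


def _failed(method: str, criterion: str, reason: str, **diag) -> CutpointResult:
    return CutpointResult(method, float("nan"), criterion, float("nan"),
                          failed=True, diagnostics={"reason": reason, **diag})


# ---------------------------------------------------------------------------
# shared scan engine
# ---------------------------------------------------------------------------

class _ScanEngine:
    """Per-candidate Cox fits over one grid, computed once and cached.

    The covariate-mode sweep (X_D plus covariates) stores the fitted
    coefficients per candidate, so chi-square/AIC (A, E1), c-index (C1, C2)
    and CPE (D1, D2) all come from a single warm-started Newton sweep.
    """

    def __init__(self, data: SurvivalDataset, grid: CandidateGrid,
                 covariate_names: Sequence[str]):
        self.data = data
        self.grid = grid
        self.covariate_names = list(covariate_names)
        self.x = data.biomarker
        self.z = data.covariates(self.covariate_names)
        self.time = data.time
        self.event = data.event
        self._cov_sweep = None
        self._strata_sweep = None
        self._logrank = None
        self._scores: dict[str, np.ndarray] = {}
        self._pairs = None

    # -- covariate-mode sweep ---------------------------------------------
    def cov_sweep(self):
        """(loglik, chi2, aic, betas, converged) arrays over the grid."""
        if self._cov_sweep is None:
            pl = PartialLikelihood(self.time, self.event)
            n, pz = self.z.shape
            p = 1 + pz
            X = np.empty((n, p))
            X[:, 1:] = self.z
            K = len(self.grid)
            ll = np.full(K, np.nan)
            betas = np.full((K, p), np.nan)
            conv = np.zeros(K, dtype=bool)
            X[:, 0] = 0.0
            ll_null = pl.loglik(X, np.zeros(p))[0]
            warm = np.zeros(p)
            for i, v in enumerate(self.grid.values):
                X[:, 0] = self.x > v
                res = _newton(pl, X, beta0=warm)
                if not res.converged:
                    res = _newton(pl, X, beta0=None)
                if res.converged:
                    warm = res.beta
                    ll[i] = res.loglik
                    betas[i] = res.beta
                    conv[i] = True
            chi2 = np.where(conv, 2.0 * (ll - ll_null), np.nan)
            aic = np.where(conv, -2.0 * ll + 2.0 * p, np.nan)
            self._cov_sweep = (ll, chi2, aic, betas, conv)
        return self._cov_sweep

    # -- concordance criteria over the same sweep -------------------------
    def criterion(self, name: str) -> np.ndarray:
        if name in self._scores:
            return self._scores[name]
        _, chi2, _, betas, conv = self.cov_sweep()
        K = len(self.grid)
        out = np.full(K, np.nan)
        n = self.x.size
        if name == "cindex":
            if self._pairs is None:
                self._pairs = ConcordancePairs(self.time, self.event)
            for i in range(K):
                if conv[i]:
                    xd = self.x > self.grid.values[i]
                    lp = betas[i, 0] * xd + self.z @ betas[i, 1:]
                    out[i] = self._pairs.cindex(lp)
        elif name == "cpe":
            Xmat = np.empty((n, 1 + self.z.shape[1]))
            Xmat[:, 1:] = self.z
            for i in range(K):
                if conv[i]:
                    Xmat[:, 0] = self.x > self.grid.values[i]
                    out[i] = gonen_heller_cpe(betas[i], Xmat)
        else:
            raise ValueError(f"unknown criterion {name!r}")
        self._scores[name] = out
        return out

    # -- strata-mode sweep (E2) -------------------------------------------
    def strata_sweep(self):
        """(aic, converged, n_infeasible) with X_D as stratum, Z as regressors."""
        if self._strata_sweep is None:
            n, pz = self.z.shape
            K = len(self.grid)
            aic = np.full(K, np.nan)
            conv = np.zeros(K, dtype=bool)
            n_infeasible = 0
            warm = np.zeros(pz)
            ev = self.event != 0
            for i, v in enumerate(self.grid.values):
                xd = self.x > v
                # every stratum needs at least one event
                if not (ev[xd].any() and ev[~xd].any()):
                    n_infeasible += 1
                    continue
                pl = PartialLikelihood(self.time, self.event, strata=xd)
                res = _newton(pl, self.z, beta0=warm)
                if not res.converged:
                    res = _newton(pl, self.z, beta0=None)
                if res.converged:
                    warm = res.beta
                    aic[i] = -2.0 * res.loglik + 2.0 * pz
                    conv[i] = True
            self._strata_sweep = (aic, conv, n_infeasible)
        return self._strata_sweep

    # -- univariable log-rank sweep (F) -----------------------------------
    def logrank_sweep(self):
        """(statistic, p_value) arrays over the grid."""
        if self._logrank is None:
            K = len(self.grid)
            stat = np.full(K, np.nan)
            pval = np.full(K, np.nan)
            for i, v in enumerate(self.grid.values):
                try:
                    res = logrank_test(self.time, self.event, self.x > v)
                except ValueError:
                    continue
                stat[i] = res.statistic
                pval[i] = res.p_value
            self._logrank = (stat, pval)
        return self._logrank


def _argbest(values: np.ndarray, maximise: bool) -> int | None:
    """Index of the best finite value; ties break to the first (smallest
    candidate, since grids are ascending).  None when nothing is finite."""
    ok = np.isfinite(values)
    if not ok.any():
        return None
    v = np.where(ok, values, -np.inf if maximise else np.inf)
    return int(np.argmax(v) if maximise else np.argmin(v))


def _stratified_half_split(event: np.ndarray, rng: np.random.Generator):
    """Random 50/50 split stratified on event status; returns boolean mask."""
    n = event.size
    in_first = np.zeros(n, dtype=bool)
    for grp in (np.flatnonzero(event == 1), np.flatnonzero(event == 0)):
        perm = rng.permutation(grp)
        in_first[perm[: grp.size // 2 + (grp.size % 2) * int(rng.random() < 0.5)]] = True
    return in_first


# ---------------------------------------------------------------------------
# methods A and B (chi-square based)
# ---------------------------------------------------------------------------

def estimate_maxchi2(
    data: SurvivalDataset,
    grid: CandidateGrid | None = None,
    covariate_names: Sequence[str] | None = None,
    _engine: _ScanEngine | None = None,
) -> CutpointResult:
    """Method A's search: the candidate with the largest model LRT chi-square."""
    engine = _engine or _make_engine(data, grid, covariate_names)
    _, chi2, _, _, conv = engine.cov_sweep()
    best = _argbest(chi2, maximise=True)
    if best is None:
        return _failed("A", "chi_square", "all fits failed", grid_size=len(engine.grid))
    return CutpointResult(
        "A", float(engine.grid.values[best]), "chi_square", float(chi2[best]),
        diagnostics={"grid_size": len(engine.grid),
                     "n_failed_fits": int((~conv).sum())})


def crossval_effect(
    data: SurvivalDataset,
    covariate_names: Sequence[str] | None = None,
    grid: CandidateGrid | None = None,
    seed: int = 0,
) -> tuple[float, float]:
    """Twofold cross-validated (hazard ratio, Wald p) for the dichotomised
    biomarker: each half is dichotomised at the cutpoint estimated (by max
    chi-square) on the *other* half, and one pooled Cox model is fitted."""
    covariate_names = list(covariate_names or data.covariate_cols)
    min_prop = grid.min_prop if grid is not None else 0.10
    rng = np.random.default_rng(seed)
    first = _stratified_half_split(data.event, rng)
    halves = [data.subset(first), data.subset(~first)]
    if any(h.n_events < 2 for h in halves):
        raise ValueError("each half needs at least two events")
    cuts = []
    for half in halves:
        g = candidate_grid(half.biomarker, min_prop)
        res = estimate_maxchi2(half, g, covariate_names)
        if res.failed:
            raise ValueError("cutpoint search failed on one half")
        cuts.append(res.cutpoint)
    xd = np.empty(data.n)
    xd[first] = dichotomise(data.biomarker[first], cuts[1])
    xd[~first] = dichotomise(data.biomarker[~first], cuts[0])
    pooled = data.data.copy()
    pooled["_XD"] = xd
    if np.ptp(xd) == 0:
        raise ValueError("pooled out-of-fold indicator is constant")
    fit = fit_cox(replace(data, data=pooled), ["_XD", *covariate_names])
    if not fit.converged:
        raise ValueError("pooled cross-validation fit did not converge")
    return fit.hazard_ratio("_XD"), fit.wald_p("_XD")


def estimate_splitsample(
    data: SurvivalDataset,
    covariate_names: Sequence[str] | None = None,
    min_prop: float = 0.10,
    seed: int = 0,
) -> CutpointResult:
    """Method B: cutpoint by max chi-square on a random half (its own grid);
    hazard ratio and p from a Cox fit on the held-out half."""
    if data.n < 40:
        raise ValueError("split-sample method needs at least 40 subjects")
    covariate_names = list(covariate_names or data.covariate_cols)
    rng = np.random.default_rng(seed)
    first = _stratified_half_split(data.event, rng)
    search, held = data.subset(first), data.subset(~first)
    g = candidate_grid(search.biomarker, min_prop)
    res = estimate_maxchi2(search, g, covariate_names)
    if res.failed:
        return _failed("B", "chi_square", "search-half scan failed")
    held_frame = held.data.copy()
    held_frame["_XD"] = dichotomise(held.biomarker, res.cutpoint)
    if np.ptp(held_frame["_XD"].to_numpy()) == 0:
        return _failed("B", "chi_square", "held-out dichotomisation is constant",
                       cutpoint=res.cutpoint)
    fit = fit_cox(replace(held, data=held_frame), ["_XD", *covariate_names])
    if not fit.converged:
        return _failed("B", "chi_square", "held-out fit did not converge",
                       cutpoint=res.cutpoint)
    return CutpointResult(
        "B", res.cutpoint, "chi_square", res.criterion_value,
        hazard_ratio=fit.hazard_ratio("_XD"), p_value=fit.wald_p("_XD"),
        diagnostics={**res.diagnostics, "split_seed": seed,
                     "n_search": search.n, "n_held": held.n})


# ---------------------------------------------------------------------------
# concordance-based methods C and D
# ---------------------------------------------------------------------------

def estimate_concordance_addfor(
    data: SurvivalDataset,
    grid: CandidateGrid | None = None,
    covariate_names: Sequence[str] | None = None,
    criterion: str = "cindex",
    _engine: _ScanEngine | None = None,
) -> CutpointResult:
    """Methods C1/D1: exhaustive grid scan maximising the c-index or CPE.

    The stepwise AddFor search reduces to the exhaustive scan when a single
    cutpoint is estimated.
    """
    if criterion not in ("cindex", "cpe"):
        raise ValueError("criterion must be 'cindex' or 'cpe'")
    method = "C1" if criterion == "cindex" else "D1"
    engine = _engine or _make_engine(data, grid, covariate_names)
    scores = engine.criterion(criterion)
    best = _argbest(scores, maximise=True)
    if best is None:
        return _failed(method, criterion, "all fits failed",
                       grid_size=len(engine.grid))
    return CutpointResult(
        method, float(engine.grid.values[best]), criterion, float(scores[best]),
        diagnostics={"grid_size": len(engine.grid),
                     "n_failed_fits": int(np.isnan(scores).sum())})


@dataclass(frozen=True)
class GASettings:
    """Real-coded genetic algorithm settings for methods C2/D2."""

    population: int = 50
    generations: int = 100
    tournament: int = 3
    mutation_prob: float = 0.3
    mutation_sd_frac: float = 0.05  # Gaussian mutation sd = range/20
    crossover_prob: float = 0.9
    elitism: int = 1
    stagnation: int = 20


def estimate_concordance_genetic(
    data: SurvivalDataset,
    bounds: tuple[float, float] | None = None,
    covariate_names: Sequence[str] | None = None,
    criterion: str = "cindex",
    ga_params: GASettings | None = None,
    seed: int = 0,
    _engine: _ScanEngine | None = None,
) -> CutpointResult:
    """Methods C2/D2: genetic algorithm over the cutpoint within bounds.

    The fitness of a cutpoint c is the criterion of the Cox fit at the
    dichotomisation 1{X > c}; it is piecewise constant between consecutive
    observed biomarker values, so fitness evaluations are memoised per piece.
    Deterministic under ``seed``.
    """
    if criterion not in ("cindex", "cpe"):
        raise ValueError("criterion must be 'cindex' or 'cpe'")
    method = "C2" if criterion == "cindex" else "D2"
    ga = ga_params or GASettings()
    engine = _engine or _make_engine(data, None, covariate_names)
    if bounds is None:
        bounds = engine.grid.bounds
    low, high = float(bounds[0]), float(bounds[1])
    if not (low < high):
        raise ValueError("bounds must satisfy low < high")
    scores = engine.criterion(criterion)
    gv = engine.grid.values

    def fitness(c: float) -> float:
        # piece index: largest grid value <= c defines the dichotomisation
        k = int(np.searchsorted(gv, c, side="right")) - 1
        k = max(k, 0)
        s = scores[k]
        return float(s) if np.isfinite(s) else -np.inf

    rng = np.random.default_rng(seed)
    pop = rng.uniform(low, high, size=ga.population)
    fit = np.array([fitness(c) for c in pop])
    n_evals = ga.population
    best_i = int(np.argmax(fit))
    best_c, best_f = float(pop[best_i]), float(fit[best_i])
    sd = ga.mutation_sd_frac * (high - low)
    stagnant = 0
    gens_run = 0
    for gens_run in range(1, ga.generations + 1):
        new = np.empty_like(pop)
        # elitism
        order = np.argsort(fit)[::-1]
        new[: ga.elitism] = pop[order[: ga.elitism]]
        for i in range(ga.elitism, ga.population):
            # tournament selection of two parents
            parents = []
            for _ in range(2):
                idx = rng.integers(0, ga.population, size=ga.tournament)
                parents.append(pop[idx[np.argmax(fit[idx])]])
            if rng.random() < ga.crossover_prob:
                a = rng.random()
                child = a * parents[0] + (1.0 - a) * parents[1]
            else:
                child = parents[0]
            if rng.random() < ga.mutation_prob:
                child += rng.normal(0.0, sd)
            new[i] = min(max(child, low), high)
        pop = new
        fit = np.array([fitness(c) for c in pop])
        n_evals += ga.population
        gen_best = int(np.argmax(fit))
        if fit[gen_best] > best_f + 1e-12:
            best_f, best_c = float(fit[gen_best]), float(pop[gen_best])
            stagnant = 0
        else:
            stagnant += 1
            if stagnant >= ga.stagnation:
                break
    failure_rate = float(np.mean(~np.isfinite(fit)))
    if not np.isfinite(best_f) or failure_rate > 0.5:
        return _failed(method, criterion, "fitness evaluation failures",
                       failure_rate=failure_rate)
    return CutpointResult(
        method, best_c, criterion, best_f,
        diagnostics={"generations": gens_run, "n_evals": n_evals,
                     "seed": seed, "bounds": (low, high)})


# ---------------------------------------------------------------------------
# AIC-based methods E1/E2 and the univariable method F
# ---------------------------------------------------------------------------

def estimate_minaic(
    data: SurvivalDataset,
    grid: CandidateGrid | None = None,
    covariate_names: Sequence[str] | None = None,
    as_strata: bool = False,
    _engine: _ScanEngine | None = None,
) -> CutpointResult:
    """Methods E1/E2: the candidate minimising the AIC, with X_D entering as a
    covariate (E1) or as a stratum with separate baseline hazards (E2)."""
    engine = _engine or _make_engine(data, grid, covariate_names)
    method = "E2" if as_strata else "E1"
    if as_strata:
        aic, conv, n_infeasible = engine.strata_sweep()
        extra = {"n_infeasible": n_infeasible}
    else:
        _, _, aic, _, conv = engine.cov_sweep()
        extra = {}
    best = _argbest(aic, maximise=False)
    if best is None:
        return _failed(method, "aic", "all candidates infeasible or failed",
                       grid_size=len(engine.grid), **extra)
    return CutpointResult(
        method, float(engine.grid.values[best]), "aic", float(aic[best]),
        diagnostics={"grid_size": len(engine.grid),
                     "n_failed_fits": int((~conv).sum()), **extra})


def estimate_minp_logrank(
    data: SurvivalDataset,
    grid: CandidateGrid | None = None,
    _engine: _ScanEngine | None = None,
) -> CutpointResult:
    """Method F: univariable minimum-p log-rank search.

    The reported minimum p is uncorrected for the search over candidates and
    is therefore selection-biased; the diagnostics note this.
    """
    engine = _engine or _make_engine(data, grid, None)
    stat, pval = engine.logrank_sweep()
    best = _argbest(stat, maximise=True)  # argmax statistic == argmin p
    if best is None:
        return _failed("F", "logrank_p", "all candidates degenerate",
                       grid_size=len(engine.grid))
    return CutpointResult(
        "F", float(engine.grid.values[best]), "logrank_p", float(pval[best]),
        p_value=float(pval[best]),
        diagnostics={"grid_size": len(engine.grid), "statistic": float(stat[best]),
                     "note": "minimum p is selection-biased (uncorrected)"})


# ---------------------------------------------------------------------------
# batch driver
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EstimateSettings:
    """Shared settings for a batch of methods."""

    min_prop: float = 0.10
    ga: GASettings = field(default_factory=GASettings)
    crossval_hr: bool = True  # compute method A's cross-validated HR and p


def _make_engine(data, grid, covariate_names, min_prop: float = 0.10) -> _ScanEngine:
    covariate_names = list(covariate_names or data.covariate_cols)
    if grid is None:
        grid = candidate_grid(data.biomarker, min_prop)
    return _ScanEngine(data, grid, covariate_names)


def estimate_all(
    data: SurvivalDataset,
    covariate_names: Sequence[str] | None = None,
    methods: Sequence[str] = METHODS,
    settings: EstimateSettings | None = None,
    seed: int = 0,
) -> list[CutpointResult]:
    """Run a subset of the methods on one dataset over a shared grid.

    Per-method randomness (A's cross-validation split, B's half split, the
    genetic algorithms) is seeded deterministically from ``seed``.  A failing
    method is recorded as a flagged result without aborting the batch.
    """
    methods = list(methods)
    if not methods:
        raise ValueError("methods must be non-empty")
    unknown = set(methods) - set(METHODS)
    if unknown:
        raise ValueError(f"unknown methods {sorted(unknown)}")
    settings = settings or EstimateSettings()
    covariate_names = list(covariate_names or data.covariate_cols)
    engine = _make_engine(data, None, covariate_names, settings.min_prop)
    grid = engine.grid
    # fixed per-method seed offsets so the subset chosen does not change them
    method_seed = {m: int(s) & 0x7FFFFFFF for m, s in zip(
        METHODS, np.random.SeedSequence(seed).generate_state(len(METHODS)))}

    results: list[CutpointResult] = []
    for method in METHODS:
        if method not in methods:
            continue
        try:
            if method == "A":
                res = estimate_maxchi2(data, grid, covariate_names, _engine=engine)
                if not res.failed and settings.crossval_hr:
                    try:
                        hr, p = crossval_effect(data, covariate_names, grid,
                                                seed=method_seed["A"])
                        res = replace(res, hazard_ratio=hr, p_value=p)
                    except ValueError as exc:
                        res = replace(res, diagnostics={
                            **res.diagnostics, "crossval_error": str(exc)})
            elif method == "B":
                res = estimate_splitsample(data, covariate_names,
                                           settings.min_prop, seed=method_seed["B"])
            elif method in ("C1", "D1"):
                res = estimate_concordance_addfor(
                    data, grid, covariate_names,
                    criterion="cindex" if method == "C1" else "cpe",
                    _engine=engine)
            elif method in ("C2", "D2"):
                res = estimate_concordance_genetic(
                    data, grid.bounds, covariate_names,
                    criterion="cindex" if method == "C2" else "cpe",
                    ga_params=settings.ga, seed=method_seed[method],
                    _engine=engine)
            elif method == "E1":
                res = estimate_minaic(data, grid, covariate_names,
                                      as_strata=False, _engine=engine)
            elif method == "E2":
                res = estimate_minaic(data, grid, covariate_names,
                                      as_strata=True, _engine=engine)
            else:
                res = estimate_minp_logrank(data, grid, _engine=engine)
        except ValueError as exc:
            res = _failed(method, "unknown", str(exc))
        results.append(res)
    return results
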