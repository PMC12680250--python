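"""Cox proportional-hazards partial likelihood and the criteria ranked by the
cutpoint methods: LRT chi-square, AIC, Harrell's c-index, the Gonen-Heller
concordance probability estimator, and the two-sample log-rank test.

The partial likelihood uses the Efron approximation for tied event times and
is maximised by Newton iterations with step-halving.  ``PartialLikelihood``
preprocesses the risk-set structure once per (time, event, strata) so that
repeated fits with different covariate matrices — the cutpoint grid scans —
pay only for the likelihood evaluations, warm-started from the neighbouring
candidate's solution.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .datasets import SurvivalDataset

try:  # compiled inner loops; the numpy paths below are the reference
    from ._kernels import concordant_pair_score as _compiled_pair_score
    from ._kernels import cox_efron_loglik as _compiled_loglik
    from ._kernels import cpe_pair_mean as _compiled_cpe
except Exception:  # pragma: no cover - numba missing or compilation failure
    _compiled_loglik = _compiled_pair_score = _compiled_cpe = None

__all__ = [
    "CoxFit",
    "LogRankResult",
    "PartialLikelihood",
    "fit_cox",
    "harrell_cindex",
    "gonen_heller_cpe",
    "logrank_test",
]

_NEWTON_TOL = 1e-9
_NEWTON_MAX_ITER = 100
_SEPARATION_BOUND = 15.0  # |beta| beyond exp(15) ~ 3e6 flags quasi-separation


@dataclass
class CoxFit:
    """Summary of one fitted Cox model."""

    names: tuple[str, ...]
    coef: np.ndarray
    cov: np.ndarray | None
    log_pl: float
    log_pl_null: float
    linear_predictors: np.ndarray
    converged: bool
    n_iter: int
    n_events: int
    flags: tuple[str, ...] = ()

    @property
    def k(self) -> int:
        """Number of estimated coefficients (strata contribute none)."""
        return len(self.coef)

    @property
    def chi_square(self) -> float:
        """Likelihood-ratio statistic 2*(log_pl - log_pl_null)."""
        return max(0.0, 2.0 * (self.log_pl - self.log_pl_null))

    @property
    def aic(self) -> float:
        return -2.0 * self.log_pl + 2.0 * self.k

    def se(self) -> np.ndarray:
        if self.cov is None:
            return np.full(self.k, np.nan)
        return np.sqrt(np.diag(self.cov))

    def hazard_ratio(self, name: str) -> float:
        return float(np.exp(self.coef[self.names.index(name)]))

    def wald_p(self, name: str) -> float:
        """Two-sided Wald p-value for one coefficient."""
        i = self.names.index(name)
        se = self.se()[i]
        if not np.isfinite(se) or se == 0:
            return float("nan")
        z = self.coef[i] / se
        return float(2.0 * stats.norm.sf(abs(z)))


class _StratumBlock:
    """Risk-set bookkeeping for one stratum, sorted by time ascending."""

    __slots__ = ("order", "ev_pos", "grp_start", "grp_end", "d", "risk_start",
                 "max_d", "n_events")

    def __init__(self, order: np.ndarray, time: np.ndarray, event: np.ndarray):
        self.order = order
        ts = time[order]
        es = event[order] != 0
        self.ev_pos = np.flatnonzero(es)
        self.n_events = self.ev_pos.size
        if self.n_events == 0:
            raise ValueError("stratum contains no events")
        ev_t = ts[self.ev_pos]
        new_grp = np.r_[True, ev_t[1:] != ev_t[:-1]]
        self.grp_start = np.flatnonzero(new_grp)
        self.grp_end = np.r_[self.grp_start[1:], ev_t.size]
        counts = self.grp_end - self.grp_start
        self.d = counts.astype(float)
        self.max_d = int(counts.max())
        self.risk_start = np.searchsorted(ts, ev_t[self.grp_start], side="left")


class PartialLikelihood:
    """Efron-tied Cox partial likelihood, optionally stratified.

    Evaluation returns (log-likelihood, gradient, Hessian) for a covariate
    matrix in the *original* row order and a coefficient vector.
    """

    def __init__(self, time, event, strata=None, engine: str = "auto"):
        if engine not in ("auto", "numpy"):
            raise ValueError("engine must be 'auto' or 'numpy'")
        self.engine = engine
        time = np.asarray(time, dtype=float)
        event = np.asarray(event)
        if time.ndim != 1 or time.shape != event.shape:
            raise ValueError("time and event must be 1-d arrays of equal length")
        self.n = time.size
        self.blocks: list[_StratumBlock] = []
        if strata is None:
            order = np.argsort(time, kind="stable")
            self.blocks.append(_StratumBlock(order, time, event))
        else:
            strata = np.asarray(strata)
            order = np.argsort(time, kind="stable")
            for lab in np.unique(strata):
                sub = order[strata[order] == lab]
                if sub.size == 0:
                    raise ValueError(f"stratum {lab!r} is empty")
                self.blocks.append(_StratumBlock(sub, time, event))
        self.n_events = sum(b.n_events for b in self.blocks)

    def loglik(self, X: np.ndarray, beta: np.ndarray):
        """Log partial likelihood with gradient and Hessian at beta."""
        X = np.asarray(X, dtype=float)
        beta = np.asarray(beta, dtype=float)
        p = X.shape[1]
        ll = 0.0
        grad = np.zeros(p)
        hess = np.zeros((p, p))
        eta_all = X @ beta
        if _compiled_loglik is not None and self.engine == "auto":
            for b in self.blocks:
                Xs = np.ascontiguousarray(X[b.order])
                eta = eta_all[b.order]
                eta = eta - eta.max()
                ll_b, g_b, h_b = _compiled_loglik(
                    Xs, eta, b.ev_pos, b.grp_start, b.grp_end, b.risk_start)
                ll += ll_b
                grad += g_b
                hess += h_b
            return ll, grad, hess
        for b in self.blocks:
            Xs = X[b.order]
            # Shift-invariance of the partial likelihood permits centering;
            # the event-sum term below must use the same centered eta.
            eta = eta_all[b.order]
            eta = eta - eta.max()
            r = np.exp(eta)
            # One packed reverse cumulative sum: [r, r*x, r*x x^T].
            packed = np.empty((Xs.shape[0], 1 + p + p * p))
            packed[:, 0] = r
            rX = r[:, None] * Xs
            packed[:, 1:1 + p] = rX
            packed[:, 1 + p:] = (rX[:, :, None] * Xs[:, None, :]).reshape(-1, p * p)
            rc = np.cumsum(packed[::-1], axis=0)[::-1]
            S = rc[b.risk_start]
            S0 = S[:, 0]
            S1 = S[:, 1:1 + p]
            S2 = S[:, 1 + p:].reshape(-1, p, p)

            ev = b.ev_pos
            gs = b.grp_start
            pe = packed[ev]
            D = np.add.reduceat(pe, gs, axis=0)
            D0 = D[:, 0]
            D1 = D[:, 1:1 + p]
            D2 = D[:, 1 + p:].reshape(-1, p, p)
            ll += float(np.add.reduceat(eta[ev], gs).sum())
            grad += np.add.reduceat(Xs[ev], gs, axis=0).sum(axis=0)

            for j in range(b.max_d):
                if j == 0:
                    mask = slice(None)
                    frac = np.zeros(len(b.d))
                else:
                    mask = b.d > j
                    frac = j / b.d[mask]
                phi = S0[mask] - frac * D0[mask]
                psi1 = S1[mask] - frac[:, None] * D1[mask]
                psi2 = S2[mask] - frac[:, None, None] * D2[mask]
                ll -= float(np.log(phi).sum())
                inv = 1.0 / phi
                xbar = psi1 * inv[:, None]
                grad -= xbar.sum(axis=0)
                hess -= np.einsum("kij,k->ij", psi2, inv) - xbar.T @ xbar
        return ll, grad, hess


@dataclass
class _NewtonResult:
    beta: np.ndarray
    loglik: float
    grad: np.ndarray
    hess: np.ndarray
    converged: bool
    n_iter: int
    flags: tuple[str, ...]


def _newton(
    pl: PartialLikelihood,
    X: np.ndarray,
    beta0: np.ndarray | None = None,
    tol: float = _NEWTON_TOL,
    max_iter: int = _NEWTON_MAX_ITER,
) -> _NewtonResult:
    p = X.shape[1]
    beta = np.zeros(p) if beta0 is None else np.array(beta0, dtype=float)
    ll, g, H = pl.loglik(X, beta)
    if not np.isfinite(ll):
        beta = np.zeros(p)
        ll, g, H = pl.loglik(X, beta)
    flags: list[str] = []
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        try:
            delta = np.linalg.solve(-H, g)
        except np.linalg.LinAlgError:
            flags.append("singular_hessian")
            break
        step = 1.0
        improved = False
        for _ in range(30):
            cand = beta + step * delta
            ll_new, g_new, H_new = pl.loglik(X, cand)
            if np.isfinite(ll_new) and ll_new >= ll - 1e-12:
                improved = True
                break
            step *= 0.5
        if not improved:
            flags.append("no_improvement")
            break
        d_ll = ll_new - ll
        beta, ll, g, H = cand, ll_new, g_new, H_new
        if abs(d_ll) <= tol * (abs(ll) + 1.0):
            converged = True
            break
    if np.max(np.abs(beta)) > _SEPARATION_BOUND:
        flags.append("separation")
        converged = False
    return _NewtonResult(beta, ll, g, H, converged, n_iter, tuple(flags))


def fit_cox(
    data: SurvivalDataset,
    covariates: Sequence[str] | None = None,
    strata: str | None = None,
    beta0: np.ndarray | None = None,
) -> CoxFit:
    """Maximise the (optionally stratified) partial likelihood.

    ``covariates`` are column names of ``data`` (default: biomarker plus the
    dataset's covariate columns); ``strata`` names a column whose distinct
    values receive separate baseline hazards and contribute no coefficients.
    The null log partial likelihood is evaluated at zero coefficients on the
    same strata structure.  Non-convergence and quasi-separation are reported
    through ``converged``/``flags``, not exceptions.
    """
    if covariates is None:
        covariates = [data.biomarker_col, *data.covariate_cols]
    covariates = list(covariates)
    if not covariates:
        raise ValueError("at least one covariate is required")
    X = data.data[covariates].to_numpy(dtype=float)
    strata_labels = data.data[strata].to_numpy() if strata is not None else None
    if strata_labels is None:
        if np.any(np.ptp(X, axis=0) == 0):
            raise ValueError("covariates must be non-constant")
    pl = PartialLikelihood(data.time, data.event, strata_labels)
    ll_null = pl.loglik(X, np.zeros(X.shape[1]))[0]
    res = _newton(pl, X, beta0=beta0)
    cov = None
    if res.converged:
        try:
            cov = np.linalg.inv(-res.hess)
        except np.linalg.LinAlgError:
            cov = None
    return CoxFit(
        names=tuple(covariates),
        coef=res.beta,
        cov=cov,
        log_pl=res.loglik,
        log_pl_null=ll_null,
        linear_predictors=X @ res.beta,
        converged=res.converged,
        n_iter=res.n_iter,
        n_events=pl.n_events,
        flags=res.flags,
    )


# ---------------------------------------------------------------------------
# concordance measures
# ---------------------------------------------------------------------------

class ConcordancePairs:
    """Comparable-pair structure of (time, event), reusable across predictors.

    A pair is comparable when the subject with the shorter observed time had
    the event; pairs tied in time are comparable only when exactly one of the
    two is an event (the censored subject is known to survive longer).
    """

    def __init__(self, time, event):
        time = np.asarray(time, dtype=float)
        event = np.asarray(event).astype(bool)
        t_i, t_j = time[:, None], time[None, :]
        e_i = event[:, None]
        earlier = (t_i < t_j) | ((t_i == t_j) & e_i & ~event[None, :])
        comparable = earlier & e_i
        np.fill_diagonal(comparable, False)
        self.i_idx, self.j_idx = np.nonzero(comparable)
        self.n_pairs = self.i_idx.size

    def cindex(self, predictor: np.ndarray) -> float:
        if self.n_pairs == 0:
            raise ValueError("no comparable pairs")
        p = np.ascontiguousarray(predictor, dtype=float)
        if _compiled_pair_score is not None:
            return _compiled_pair_score(p, self.i_idx, self.j_idx) / self.n_pairs
        pi, pj = p[self.i_idx], p[self.j_idx]
        concordant = np.count_nonzero(pi > pj)
        tied = np.count_nonzero(pi == pj)
        return (concordant + 0.5 * tied) / self.n_pairs


def harrell_cindex(linear_predictors, time, event) -> float:
    """Harrell's c-index: share of comparable pairs ranked concordantly.

    The subject with the shorter observed event time should carry the higher
    linear predictor; predictor ties count 1/2.
    """
    return ConcordancePairs(time, event).cindex(linear_predictors)


def gonen_heller_cpe(coefficients, covariates) -> float:
    """Gonen-Heller concordance probability estimator K(beta).

    Computed from the fitted coefficients and covariate pairs only, hence
    robust to censoring by construction:
    mean over unordered pairs of 1/(1 + exp(-|beta'(x_i - x_j)|)),
    with pairs at zero difference contributing 1/2.
    """
    beta = np.asarray(coefficients, dtype=float)
    x = np.asarray(covariates, dtype=float)
    n = x.shape[0]
    if n < 2:
        raise ValueError("CPE needs at least two subjects")
    eta = np.ascontiguousarray(x @ beta)
    if _compiled_cpe is not None:
        return float(_compiled_cpe(eta))
    iu, ju = np.triu_indices(n, k=1)
    delta = np.abs(eta[iu] - eta[ju])
    return float(np.mean(1.0 / (1.0 + np.exp(-delta))))


# ---------------------------------------------------------------------------
# log-rank test
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LogRankResult:
    statistic: float
    p_value: float


def logrank_test(time, event, group) -> LogRankResult:
    """Two-sample log-rank test with the hypergeometric variance.

    statistic = (sum_d (O_1d - E_1d))^2 / sum_d V_1d over distinct event
    times d; p-value from the 1-df chi-square upper tail.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event).astype(bool)
    group = np.asarray(group).astype(bool)
    if group.all() or (~group).all():
        raise ValueError("both groups must be non-empty")
    if not event.any():
        raise ValueError("at least one event is required")

    order = np.argsort(time, kind="stable")
    ts, es, gs = time[order], event[order], group[order]
    n = ts.size
    ev_t = ts[es]
    uniq = np.unique(ev_t)
    # Subjects at risk just before each event time.
    at_risk = n - np.searchsorted(ts, uniq, side="left")
    cum_g = np.concatenate([[0], np.cumsum(gs)])
    at_risk_1 = cum_g[-1] - cum_g[np.searchsorted(ts, uniq, side="left")]
    # Death counts per unique event time (total and in group 1).
    d_tot = np.searchsorted(np.sort(ev_t), uniq, side="right") - np.searchsorted(
        np.sort(ev_t), uniq, side="left")
    ev_g = ts[es & gs]
    d_1 = np.searchsorted(np.sort(ev_g), uniq, side="right") - np.searchsorted(
        np.sort(ev_g), uniq, side="left")

    frac = at_risk_1 / at_risk
    e_1 = d_tot * frac
    with np.errstate(invalid="ignore", divide="ignore"):
        v = np.where(
            at_risk > 1,
            d_tot * frac * (1.0 - frac) * (at_risk - d_tot) / (at_risk - 1.0),
            0.0,
        )
    v_sum = float(v.sum())
    if v_sum <= 0.0:
        raise ValueError("log-rank variance is zero (degenerate risk sets)")
    stat = float((d_1 - e_1).sum() ** 2 / v_sum)
    return LogRankResult(statistic=stat, p_value=float(stats.chi2.sf(stat, df=1)))
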