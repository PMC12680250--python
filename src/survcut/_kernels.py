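"""Compiled inner loop of the Efron partial likelihood.

One reverse pass over the time-sorted subjects accumulates the risk-set sums
S0, S1, S2 and applies the Efron tie correction per unique event time.  The
numpy implementation in :mod:`survcut.cox` computes the same quantities and
serves as the reference; this kernel only removes the per-call overhead that
dominates the cutpoint grid scans.
"""
from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["cox_efron_loglik", "concordant_pair_score", "cpe_pair_mean"]


@njit(cache=True)
def concordant_pair_score(pred, i_idx, j_idx):
    """Concordant count plus half the predictor-tied count over given pairs."""
    score = 0.0
    for k in range(i_idx.shape[0]):
        a = pred[i_idx[k]]
        b = pred[j_idx[k]]
        if a > b:
            score += 1.0
        elif a == b:
            score += 0.5
    return score


@njit(cache=True)
def cpe_pair_mean(eta):
    """Mean over unordered pairs of 1/(1 + exp(-|eta_i - eta_j|))."""
    n = eta.shape[0]
    total = 0.0
    for i in range(n - 1):
        ei = eta[i]
        for j in range(i + 1, n):
            d = ei - eta[j]
            if d < 0.0:
                d = -d
            total += 1.0 / (1.0 + np.exp(-d))
    return total / (n * (n - 1) / 2.0)


@njit(cache=True, fastmath=False)
def cox_efron_loglik(Xs, eta, ev_pos, grp_start, grp_end, risk_start):
    """(log-PL, gradient, Hessian) for one stratum, sorted by time ascending.

    ev_pos: sorted-array positions of the events, grouped by tied event time
    via [grp_start[k], grp_end[k]); risk_start[k] is the first sorted index
    belonging to the k-th risk set.  eta must be pre-centered by the caller.
    """
    m, p = Xs.shape
    K = grp_start.shape[0]
    ll = 0.0
    grad = np.zeros(p)
    hess = np.zeros((p, p))
    acc0 = 0.0
    acc1 = np.zeros(p)
    acc2 = np.zeros((p, p))
    d1 = np.zeros(p)
    d2 = np.zeros((p, p))
    pos = m - 1
    for k in range(K - 1, -1, -1):
        while pos >= risk_start[k]:
            r = np.exp(eta[pos])
            acc0 += r
            for a in range(p):
                ra = r * Xs[pos, a]
                acc1[a] += ra
                for b in range(a + 1):
                    acc2[a, b] += ra * Xs[pos, b]
            pos -= 1
        # event-group sums (numerator and Efron tie adjustments)
        d0 = 0.0
        for a in range(p):
            d1[a] = 0.0
            for b in range(a + 1):
                d2[a, b] = 0.0
        dk = grp_end[k] - grp_start[k]
        for e in range(grp_start[k], grp_end[k]):
            i = ev_pos[e]
            ll += eta[i]
            r = np.exp(eta[i])
            d0 += r
            for a in range(p):
                grad[a] += Xs[i, a]
                ra = r * Xs[i, a]
                d1[a] += ra
                for b in range(a + 1):
                    d2[a, b] += ra * Xs[i, b]
        for j in range(dk):
            frac = j / dk
            phi = acc0 - frac * d0
            ll -= np.log(phi)
            inv = 1.0 / phi
            for a in range(p):
                xa = (acc1[a] - frac * d1[a]) * inv
                grad[a] -= xa
                for b in range(a + 1):
                    xb = (acc1[b] - frac * d1[b]) * inv
                    hess[a, b] -= (acc2[a, b] - frac * d2[a, b]) * inv - xa * xb
    for a in range(p):
        for b in range(a):
            hess[b, a] = hess[a, b]
    return ll, grad, hess
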