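"""Lightweight Cox partial-likelihood Newton solver for permutation loops.

Refit-based permutation tests need thousands of Cox fits per gene; this
module provides a minimal, vectorized Efron-tie Newton-Raphson fitter with
a Breslow baseline cumulative hazard, trading the diagnostics of the full
fitter in :mod:`routesurv.survival` for speed.  Agreement with the full
fitter is asserted in the test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = ["fast_cox", "per_case_rms"]


def _loglik_grad_hess(times, events, X, beta):
    """Efron-corrected partial log-likelihood, gradient, Hessian.

    ``times`` must be sorted ascending; suffix sums give risk-set
    aggregates.  The tie correction only engages for duplicated event
    times (continuous data hits the d=1 fast path).
    """
    n, p = X.shape
    eta = X @ beta
    eta = np.clip(eta, -200, 200)
    w = np.exp(eta)
    wx = w[:, None] * X
    # suffix (risk-set) sums: entry i aggregates j >= i in time order
    s0 = np.cumsum(w[::-1])[::-1]
    s1 = np.cumsum(wx[::-1], axis=0)[::-1]
    wxx = wx[:, :, None] * X[:, None, :]
    s2 = np.cumsum(wxx[::-1], axis=0)[::-1]

    ev = np.nonzero(events)[0]
    if ev.size == 0:
        raise ValueError("no events")
    t_ev = times[ev]
    # risk sets must include censored cases tied at the event time, which may
    # sort before the event: aggregate from the first occurrence of the time
    risk_idx = np.searchsorted(times, t_ev, side="left")
    unique_starts = np.nonzero(np.concatenate([[True], np.diff(t_ev) > 0]))[0]
    d_sizes = np.diff(np.concatenate([unique_starts, [ev.size]]))

    if d_sizes.max() == 1:
        # no tied events: Efron == Breslow, fully vectorized
        r0 = s0[risk_idx]
        r1 = s1[risk_idx]
        r2 = s2[risk_idx]
        mu = r1 / r0[:, None]
        ll = float(np.sum(eta[ev] - np.log(r0)))
        grad = np.sum(X[ev] - mu, axis=0)
        hess = -np.sum(r2 / r0[:, None, None] - mu[:, :, None] * mu[:, None, :], axis=0)
        return ll, grad, hess

    ll = 0.0
    grad = np.zeros(p)
    hess = np.zeros((p, p))
    for gi, start in enumerate(unique_starts):
        d = d_sizes[gi]
        members = ev[start : start + d]
        first = risk_idx[start]
        r0, r1, r2 = s0[first], s1[first], s2[first]
        wd = w[members].sum()
        wd1 = wx[members].sum(axis=0)
        wd2 = wxx[members].sum(axis=0)
        ll += float(eta[members].sum())
        for l in range(d):
            f = l / d
            a0 = r0 - f * wd
            a1 = r1 - f * wd1
            a2 = r2 - f * wd2
            mu = a1 / a0
            ll -= np.log(a0)
            grad += -mu
            hess -= a2 / a0 - np.outer(mu, mu)
        grad += X[members].sum(axis=0)
    return ll, grad, hess


def fast_cox(times, events, X, *, tol: float = 1e-9, max_iter: int = 60, beta0=None):
    """Newton-Raphson maximum partial likelihood.

    Returns (beta, baseline_times, baseline_cumhaz) where the baseline is
    the Breslow cumulative hazard at the zero covariate vector.  Inputs
    need not be sorted.  ``beta0`` warm-starts the iteration (useful in
    permutation loops where successive fits are near each other).
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    X = np.asarray(X, dtype=float)
    order = np.argsort(times, kind="stable")
    t = times[order]
    e = events[order]
    Xs = X[order]
    n, p = Xs.shape

    beta = np.zeros(p) if beta0 is None else np.asarray(beta0, dtype=float).copy()
    ll, grad, hess = _loglik_grad_hess(t, e, Xs, beta)
    for _ in range(max_iter):
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(hess, grad, rcond=None)[0]
        new = beta - step
        ll_new, grad_new, hess_new = _loglik_grad_hess(t, e, Xs, new)
        halves = 0
        while (not np.isfinite(ll_new) or ll_new < ll - 1e-12) and halves < 30:
            step = step / 2
            new = beta - step
            ll_new, grad_new, hess_new = _loglik_grad_hess(t, e, Xs, new)
            halves += 1
        beta, ll, grad, hess = new, ll_new, grad_new, hess_new
        if np.linalg.norm(grad) < tol:
            break

    # Breslow/Efron baseline cumulative hazard at x = 0
    w = np.exp(np.clip(Xs @ beta, -200, 200))
    s0 = np.cumsum(w[::-1])[::-1]
    ev = np.nonzero(e)[0]
    t_ev = t[ev]
    risk_idx = np.searchsorted(t, t_ev, side="left")
    unique_starts = np.nonzero(np.concatenate([[True], np.diff(t_ev) > 0]))[0]
    d_sizes = np.diff(np.concatenate([unique_starts, [ev.size]]))
    bt = t_ev[unique_starts]
    increments = np.empty(bt.size)
    # Breslow-type baseline: d / S0 per distinct event time
    increments = d_sizes / s0[risk_idx[unique_starts]]
    H0 = np.cumsum(increments)
    return beta, bt, H0


def per_case_rms(beta, bt, H0, X, tau: float = 60.0) -> np.ndarray:
    """Vectorized restricted mean survival for rows of X under a fast fit.

    RMS_i = area to tau under S_i(t) = exp(-H0(t) exp(x_i beta)), using the
    right-continuous step convention (S = 1 before the first event time).
    """
    X = np.asarray(X, dtype=float)
    lp = np.clip(X @ beta, -200, 200)
    mask = bt < tau
    grid = np.concatenate([[0.0], bt[mask], [tau]])
    widths = np.diff(grid)
    # survival at the left edge of each interval: S=1 on [0, t1)
    H_left = np.concatenate([[0.0], H0[mask]])
    S = np.exp(-np.outer(np.exp(lp), H_left))
    return S @ widths
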