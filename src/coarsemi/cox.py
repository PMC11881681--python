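"""Cox proportional-hazards fitting via Newton-Raphson.

A lean, fully vectorized partial-likelihood maximizer (Efron tie handling)
returning the MLE, the inverse observed information and a Breslow-type
baseline cumulative hazard.  The sampler-facing pieces of this package call
a Cox fit thousands of times per run, so the fit is written directly on
numpy arrays; correctness is pinned against lifelines in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["CoxFit", "fit_cox", "breslow_cumhaz", "CoxError"]


class CoxError(RuntimeError):
    """Degenerate or non-convergent Cox fit (no events, singular information)."""


@dataclass
class CoxFit:
    coef: np.ndarray          # (p,) log hazard ratios
    cov: np.ndarray           # (p, p) inverse observed information
    loglik: float
    n_iter: int
    # sorted copies kept for baseline-hazard evaluation
    _order: np.ndarray = None
    _time: np.ndarray = None
    _status: np.ndarray = None
    _X: np.ndarray = None


def fit_cox(X, time, status, max_iter: int = 60, tol: float = 1e-9) -> CoxFit:
    """Maximize the Cox partial likelihood (Efron ties).

    Parameters are the covariate matrix (n, p), positive follow-up times and
    the 0/1 event indicator.  Raises :class:`CoxError` when there are no
    events or the information matrix is singular/non-finite.
    """
    X = np.asarray(X, dtype=float)
    time = np.asarray(time, dtype=float)
    status = np.asarray(status)
    n, p = X.shape
    if status.sum() == 0:
        raise CoxError("no events: partial likelihood is degenerate")

    order = np.argsort(time, kind="stable")
    Xo = X[order]
    to = time[order]
    so = status[order].astype(bool)

    # tie structure (computed once): for each event, its tie-group id and the
    # within-group fraction l/d of the Efron correction
    ev = np.flatnonzero(so)
    et = to[ev]
    grp_start = np.flatnonzero(np.r_[True, et[1:] != et[:-1]])
    grp_id = np.cumsum(np.r_[True, et[1:] != et[:-1]]) - 1
    d_per_grp = np.bincount(grp_id)
    frac = (np.arange(len(ev)) - grp_start[grp_id]) / d_per_grp[grp_id]
    # first row (sorted order) carrying each group's event time — censored
    # rows tied with an event time belong to the risk set too
    first_row = np.searchsorted(to, et[grp_start], side="left")[grp_id]

    beta = np.zeros(p)
    delta = np.full(p, np.inf)
    for it in range(1, max_iter + 1):
        eta = Xo @ beta
        shift = eta.max()
        w = np.exp(eta - shift)
        wX = w[:, None] * Xo
        S0 = np.cumsum(w[::-1])[::-1]
        S1 = np.cumsum(wX[::-1], axis=0)[::-1]
        wXX = np.einsum("ij,ik->ijk", wX, Xo)
        S2 = np.cumsum(wXX[::-1], axis=0)[::-1]

        # per-group sums over the tied deaths (Efron)
        gw = np.bincount(grp_id, weights=w[ev])
        gX = np.vstack([np.bincount(grp_id, weights=wX[ev][:, j]) for j in range(p)]).T
        gXX = np.stack(
            [[np.bincount(grp_id, weights=wXX[ev][:, j, k]) for k in range(p)]
             for j in range(p)], axis=0,
        ).transpose(2, 0, 1)

        s0 = S0[first_row] - frac * gw[grp_id]
        s1 = S1[first_row] - frac[:, None] * gX[grp_id]
        s2 = S2[first_row] - frac[:, None, None] * gXX[grp_id]

        xbar = s1 / s0[:, None]
        U = Xo[ev].sum(axis=0) - xbar.sum(axis=0)
        info = (s2 / s0[:, None, None]).sum(axis=0) - np.einsum("ij,ik->jk", xbar, xbar)
        ll = (eta[ev] - shift).sum() - np.log(s0).sum()

        if not np.all(np.isfinite(info)) or not np.all(np.isfinite(U)):
            raise CoxError("non-finite score/information (separation?)")
        try:
            delta = np.linalg.solve(info, U)
        except np.linalg.LinAlgError as e:
            raise CoxError(f"singular information matrix: {e}") from e
        beta = beta + delta
        if np.max(np.abs(delta)) < tol:
            break
    else:
        if np.max(np.abs(delta)) > 1e-4:
            raise CoxError("Newton iteration did not converge")

    cov = np.linalg.inv(info)
    return CoxFit(coef=beta, cov=cov, loglik=float(ll), n_iter=it,
                  _order=order, _time=to, _status=so, _X=Xo)


def breslow_cumhaz(fit: CoxFit, eval_times, beta: np.ndarray | None = None) -> np.ndarray:
    """Breslow baseline cumulative hazard evaluated at ``eval_times``.

    H0(t) = sum over event times s <= t of d(s) / sum_{at risk at s} exp(x'b).
    A coefficient vector other than the MLE may be supplied (used when the
    baseline must be consistent with a posterior draw of the coefficients).
    """
    beta = fit.coef if beta is None else np.asarray(beta, dtype=float)
    to, so, Xo = fit._time, fit._status, fit._X
    eta = Xo @ beta
    w = np.exp(eta - eta.max())
    S0 = np.cumsum(w[::-1])[::-1] * np.exp(eta.max())
    ev = np.flatnonzero(so)
    et = to[ev]
    # collapse ties: one increment d/S0 per unique event time
    uniq, first = np.unique(et, return_index=True)
    d = np.bincount(np.searchsorted(uniq, et))
    inc = d / S0[ev[first]]
    H = np.cumsum(inc)
    eval_times = np.asarray(eval_times, dtype=float)
    idx = np.searchsorted(uniq, eval_times, side="right") - 1
    return np.where(idx >= 0, H[np.clip(idx, 0, None)], 0.0)
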