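"""Cox proportional-hazards core: Newton-Raphson partial likelihood with
Breslow tie handling, model-based (inverse observed information) and
Lin-Wei robust (score-residual sandwich) covariance estimates.

Written for genome scans: the survival-time sort structure is shared across
loci via :class:`CoxData`, so per-locus work is O(n k^2).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class CoxData:
    """Sorted survival data reusable across many design matrices."""

    order: np.ndarray        # indices sorting time descending
    time: np.ndarray         # sorted descending
    event: np.ndarray        # bool, sorted
    risk_idx: np.ndarray     # per position: last index of its tie group
    entry_idx: np.ndarray    # per position: first index of its tie group
    inv_order: np.ndarray

    @classmethod
    def from_arrays(cls, time: np.ndarray, status: np.ndarray) -> "CoxData":
        time = np.asarray(time, dtype=float)
        status = np.asarray(status)
        n = len(time)
        order = np.argsort(-time, kind="stable")
        t = time[order]
        d = status[order].astype(bool)
        uniq, inv = np.unique(-t, return_inverse=True)
        last = np.zeros(len(uniq), dtype=np.intp)
        np.maximum.at(last, inv, np.arange(n))
        first = np.full(len(uniq), n, dtype=np.intp)
        np.minimum.at(first, inv, np.arange(n))
        inv_order = np.empty(n, dtype=np.intp)
        inv_order[order] = np.arange(n)
        return cls(order=order, time=t, event=d, risk_idx=last[inv],
                   entry_idx=first[inv], inv_order=inv_order)

    @property
    def n(self) -> int:
        return len(self.time)

    @property
    def n_events(self) -> int:
        return int(self.event.sum())


def _risk_sums(cd: CoxData, w: np.ndarray, Xs: np.ndarray):
    """Breslow risk-set sums S0, S1, S2 at every position (ties pooled)."""
    cw = np.cumsum(w)
    cwx = np.cumsum(w[:, None] * Xs, axis=0)
    cwxx = np.cumsum(w[:, None, None] * (Xs[:, :, None] * Xs[:, None, :]), axis=0)
    idx = cd.risk_idx
    return cw[idx], cwx[idx], cwxx[idx]


def _loglik(cd: CoxData, Xs: np.ndarray, beta: np.ndarray) -> float:
    eta = Xs @ beta
    eta = eta - eta.max()
    w = np.exp(eta)
    S0 = np.cumsum(w)[cd.risk_idx]
    d = cd.event
    return float((eta[d] - np.log(S0[d])).sum())


def cox_newton(cd: CoxData, X: np.ndarray, max_iter: int = 25,
               tol: float = 1e-8):
    """Maximize the Breslow partial likelihood by Newton-Raphson.

    Returns ``(beta, cov_model, cov_robust, converged, loglik)``.
    ``X`` is in original subject order; no intercept column (the baseline
    hazard absorbs it).  Step-halving is applied whenever a full Newton step
    would decrease the partial likelihood.
    """
    n, k = X.shape
    Xs = X[cd.order]
    d = cd.event
    beta = np.zeros(k)
    converged = False
    U = np.zeros(k)
    info = np.eye(k)
    try:
        for _ in range(max_iter):
            eta = Xs @ beta
            eta = eta - eta.max()
            w = np.exp(eta)
            S0, S1, S2 = _risk_sums(cd, w, Xs)
            xbar = S1 / S0[:, None]
            U = (Xs[d] - xbar[d]).sum(axis=0)
            info = (S2[d] / S0[d, None, None]
                    - xbar[d][:, :, None] * xbar[d][:, None, :]).sum(axis=0)
            if np.linalg.norm(U) < tol:
                converged = True
                break
            ll = float((eta[d] - np.log(S0[d])).sum())
            step = np.linalg.solve(info, U)
            for _ in range(11):
                cand = beta + step
                if _loglik(cd, Xs, cand) >= ll - 1e-12:
                    break
                step = step / 2.0
            beta = beta + step
    except np.linalg.LinAlgError:
        return beta, np.full((k, k), np.nan), np.full((k, k), np.nan), False, np.nan

    # quantities at the final beta
    eta = Xs @ beta
    eta = eta - eta.max()
    w = np.exp(eta)
    S0, S1, S2 = _risk_sums(cd, w, Xs)
    xbar = S1 / S0[:, None]
    U = (Xs[d] - xbar[d]).sum(axis=0)
    info = (S2[d] / S0[d, None, None]
            - xbar[d][:, :, None] * xbar[d][:, None, :]).sum(axis=0)
    converged = converged or np.linalg.norm(U) < tol
    loglik = float((eta[d] - np.log(S0[d])).sum())
    try:
        cov_model = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        return beta, np.full((k, k), np.nan), np.full((k, k), np.nan), False, loglik

    # Lin-Wei score residuals.  For subject i:
    #   s_i = d_i (x_i - xbar(t_i))
    #         - w_i * sum_{event times t_e <= t_i} (x_i - xbar(t_e)) / S0(t_e)
    ev = np.where(d, 1.0, 0.0) / S0
    A = np.cumsum(ev[::-1])[::-1][cd.entry_idx]
    B = np.cumsum((ev[:, None] * xbar)[::-1], axis=0)[::-1][cd.entry_idx]
    S = np.zeros((n, k))
    S[d] = Xs[d] - xbar[d]
    S -= w[:, None] * (A[:, None] * Xs - B)
    cov_robust = cov_model @ (S.T @ S) @ cov_model
    return beta, cov_model, cov_robust, converged, loglik
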