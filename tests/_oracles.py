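"""Independent brute-force oracles used by the test suite.

Deliberately written as plain loops and generic optimizers that share no
code with the package implementation."""

import numpy as np


def ols_sandwich_bruteforce(y, X, flavor="hc3"):
    n, k = X.shape
    XtXi = np.linalg.inv(X.T @ X)
    beta = XtXi @ X.T @ y
    r = y - X @ beta
    meat = np.zeros((k, k))
    for i in range(n):
        xi = X[i]
        h = float(xi @ XtXi @ xi)
        w = {"hc0": 1.0, "hc1": n / (n - k), "hc2": 1 / (1 - h),
             "hc3": 1 / (1 - h) ** 2}[flavor]
        meat += np.outer(xi, xi) * r[i] ** 2 * w
    return beta, XtXi @ meat @ XtXi


def logistic_nll(beta, y, X):
    eta = X @ beta
    return float(np.sum(np.log1p(np.exp(eta)) - y * eta))


def cox_partial_loglik_bruteforce(beta, t, status, X):
    eta = X @ np.atleast_1d(beta)
    ll = 0.0
    for i in range(len(t)):
        if status[i]:
            risk = t >= t[i]
            ll += eta[i] - np.log(np.exp(eta[risk]).sum())
    return ll


def cox_sandwich_bruteforce(beta, t, status, X):
    """Lin-Wei robust covariance by direct O(n^2) summation."""
    n, k = X.shape
    w = np.exp(X @ beta)
    info = np.zeros((k, k))
    xbar = {}
    s0 = {}
    for i in range(n):
        if not status[i]:
            continue
        risk = t >= t[i]
        s0[i] = w[risk].sum()
        xbar[i] = (w[risk, None] * X[risk]).sum(axis=0) / s0[i]
        s2 = sum(w[j] * np.outer(X[j], X[j]) for j in np.where(risk)[0])
        info += s2 / s0[i] - np.outer(xbar[i], xbar[i])
    S = np.zeros((n, k))
    for i in range(n):
        if status[i]:
            S[i] += X[i] - xbar[i]
        for j in s0:
            if t[j] <= t[i]:
                S[i] -= w[i] * (X[i] - xbar[j]) / s0[j]
    Iinv = np.linalg.inv(info)
    return Iinv, Iinv @ (S.T @ S) @ Iinv
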