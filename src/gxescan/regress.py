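"""Per-locus GxE interaction fits with model-based and sandwich variances.

For each locus the fitted model is the linear interaction regression

    g(E[Y]) = b0 + bE*E + bG*G + bGE*(G x E)  [+ covariates]

with identity link (least squares), logit link (logistic regression) or the
Cox log-hazard (no intercept).  Every fit carries two covariance estimates:

* ``cov_model`` — the classical estimate that trusts the mean model and
  (for least squares) homoskedasticity: sigma^2 (X'X)^-1, the inverse
  Fisher information, or the inverse observed partial-likelihood
  information;
* ``cov_robust`` — the heteroskedasticity-consistent sandwich A^-1 B A^-1
  built from estimating-equation theory (Huber-White; Lin-Wei score
  residuals for Cox), valid without trusting the mean/variance model.

The least-squares sandwich supports the HC0-HC3 small-sample flavors; the
default HC3 divides squared residuals by (1-h_ii)^2, which keeps the robust
Wald test close to nominal at cohort sizes in the low thousands.  Logistic
and Cox sandwiches are the plain (unadjusted) A^-1 B A^-1.

``genome_scan`` applies one family's fit to every genotype column and
assembles the per-locus table consumed by the genomic-control diagnostics.
Loci with minor-allele count below ``mac_min`` (default 5) and loci whose
fit fails are flagged with a status code and excluded from lambda.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._cox import CoxData, cox_newton
from .errors import ConfigError, DataError, GxescanError, NotSupportedError
from .gcdiag import (RESULT_COLUMNS, STATUS_LOW_MAC, STATUS_NOT_CONVERGED,
                     STATUS_OK, ScanResult)
from .sim import Cohort

logger = logging.getLogger(__name__)

HC_FLAVORS = ("hc0", "hc1", "hc2", "hc3")
DEFAULT_HC = "hc3"

_P_FLOOR = 1e-300       # keep reported p-values inside (0, 1]


# ----------------------------------------------------------------------
# Result containers
# ----------------------------------------------------------------------
@dataclass
class GxEFit:
    """One locus's fitted interaction model."""

    coefficients: np.ndarray
    names: list[str]
    cov_model: np.ndarray
    cov_robust: np.ndarray
    converged: bool
    n_used: int
    family: str
    loglik: float = np.nan
    idx_g: int | None = None
    idx_ge: int | None = None

    @property
    def beta_ge(self) -> float:
        return float(self.coefficients[self.idx_ge])

    def se(self, flavor: str, idx: int | None = None) -> float:
        cov = self._cov(flavor)
        idx = self.idx_ge if idx is None else idx
        return float(np.sqrt(cov[idx, idx]))

    def _cov(self, flavor: str) -> np.ndarray:
        if flavor == "model":
            return self.cov_model
        if flavor == "robust":
            return self.cov_robust
        raise ConfigError(f"se flavor must be 'model' or 'robust', got {flavor!r}")


@dataclass
class TestResult:
    statistic: float
    df: int
    p_value: float
    se_flavor: str | None
    test_kind: str


# ----------------------------------------------------------------------
# Design matrix assembly
# ----------------------------------------------------------------------
def _design(e, g, covariates, intercept: bool):
    """Columns in fixed order: [const], E, [G, GxE], covariates."""
    e = np.asarray(e, dtype=float)
    cols, names = [], []
    if intercept:
        cols.append(np.ones_like(e))
        names.append("const")
    cols.append(e)
    names.append("e")
    idx_g = idx_ge = None
    if g is not None:
        g = np.asarray(g, dtype=float)
        idx_g = len(cols)
        cols.append(g)
        names.append("g")
        idx_ge = len(cols)
        cols.append(g * e)
        names.append("g:e")
    if covariates is not None:
        C = np.atleast_2d(np.asarray(covariates, dtype=float))
        if C.shape[0] != len(e):
            C = C.T
        for q in range(C.shape[1]):
            cols.append(C[:, q])
            names.append(f"c{q + 1}")
    X = np.column_stack(cols)
    return X, names, idx_g, idx_ge


def _hc_weights(r2: np.ndarray, h: np.ndarray, n: int, k: int, hc: str) -> np.ndarray:
    if hc == "hc0":
        return r2
    if hc == "hc1":
        return r2 * (n / (n - k))
    if hc == "hc2":
        return r2 / (1.0 - h)
    if hc == "hc3":
        return r2 / (1.0 - h) ** 2
    raise ConfigError(f"unknown sandwich flavor {hc!r}; choose from {HC_FLAVORS}")


# ----------------------------------------------------------------------
# Linear family
# ----------------------------------------------------------------------
def fit_linear_gxe(y, e, g, covariates=None, hc: str = DEFAULT_HC) -> GxEFit:
    """Ordinary least squares for Y on (1, E, G, GxE, covariates).

    ``cov_model`` is sigma_hat^2 (X'X)^-1 with the usual n-k denominator;
    ``cov_robust`` is the HC sandwich (X'X)^-1 (sum_i x_i x_i' w_i) (X'X)^-1
    with w_i the HC-weighted squared residuals.  A rank-deficient design
    (e.g. a monomorphic locus) yields a flagged non-converged fit rather
    than an exception.  ``g=None`` fits the no-genotype null model (used by
    the likelihood-ratio test).
    """
    y = np.asarray(y, dtype=float)
    X, names, idx_g, idx_ge = _design(e, g, covariates, intercept=True)
    n, k = X.shape
    if len(y) != n:
        raise DataError("y length does not match design")
    nan_cov = np.full((k, k), np.nan)
    fail = GxEFit(np.full(k, np.nan), names, nan_cov, nan_cov, False, n,
                  "linear", idx_g=idx_g, idx_ge=idx_ge)
    XtX = X.T @ X
    if np.linalg.matrix_rank(XtX, hermitian=True) < k:
        return fail
    XtXi = np.linalg.inv(XtX)
    beta = XtXi @ (X.T @ y)
    r = y - X @ beta
    dof = max(n - k, 1)
    sigma2 = float(r @ r) / dof
    cov_model = sigma2 * XtXi
    h = np.einsum("ij,jk,ik->i", X, XtXi, X)
    w = _hc_weights(r ** 2, np.minimum(h, 1.0 - 1e-12), n, k, hc)
    meat = (X * w[:, None]).T @ X
    cov_robust = XtXi @ meat @ XtXi
    # Gaussian log-likelihood at the MLE variance (for likelihood-ratio tests)
    s2_mle = float(r @ r) / n
    loglik = -0.5 * n * (np.log(2 * np.pi * s2_mle) + 1.0) if s2_mle > 0 else np.inf
    return GxEFit(beta, names, cov_model, cov_robust, True, n, "linear",
                  loglik=loglik, idx_g=idx_g, idx_ge=idx_ge)


def _linear_scan_batch(y, e, G, covariates=None, hc: str = DEFAULT_HC,
                       chunk: int = 512):
    """Vectorized per-locus least squares for a genotype matrix.

    Returns (beta_ge, var_model_ge, var_robust_ge, ok) arrays of length m.
    Algebraically identical to calling :func:`fit_linear_gxe` per column;
    kept vectorized because a scan fits 10^4 separate design matrices.
    """
    y = np.asarray(y, dtype=float)
    e = np.asarray(e, dtype=float)
    G = np.asarray(G, dtype=float)
    n, m = G.shape
    base, _, _, _ = _design(e, None, covariates, intercept=True)
    nb = base.shape[1]
    k = nb + 2
    beta_ge = np.full(m, np.nan)
    vm = np.full(m, np.nan)
    vr = np.full(m, np.nan)
    ok = np.zeros(m, dtype=bool)
    for s in range(0, m, chunk):
        Gc = G[:, s:s + chunk]
        mm = Gc.shape[1]
        X = np.empty((mm, n, k))
        X[:, :, :2] = base[None, :, :2]
        X[:, :, 2] = Gc.T
        X[:, :, 3] = (Gc * e[:, None]).T
        if nb > 2:
            X[:, :, 4:] = base[None, :, 2:]
        XtX = np.einsum("lnk,lnj->lkj", X, X)
        Xty = np.einsum("lnk,n->lk", X, y)
        try:
            XtXi = np.linalg.inv(XtX)
        except np.linalg.LinAlgError:
            # fall back locus by locus inside this chunk
            for j in range(mm):
                f = fit_linear_gxe(y, e, Gc[:, j], covariates, hc=hc)
                if f.converged:
                    beta_ge[s + j] = f.beta_ge
                    vm[s + j] = f.cov_model[f.idx_ge, f.idx_ge]
                    vr[s + j] = f.cov_robust[f.idx_ge, f.idx_ge]
                    ok[s + j] = True
            continue
        beta = np.einsum("lkj,lj->lk", XtXi, Xty)
        r = y[None, :] - np.einsum("lnk,lk->ln", X, beta)
        sigma2 = (r ** 2).sum(axis=1) / (n - k)
        h = np.einsum("lnk,lkj,lnj->ln", X, XtXi, X)
        w = _hc_weights(r ** 2, np.minimum(h, 1.0 - 1e-12), n, k, hc)
        meat = np.einsum("lnk,lnj,ln->lkj", X, X, w)
        covr = XtXi @ meat @ XtXi
        # column index 3 is GxE in both the batched and single-fit layouts
        ge = 3
        beta_ge[s:s + mm] = beta[:, ge]
        vm[s:s + mm] = XtXi[:, ge, ge] * sigma2
        vr[s:s + mm] = covr[:, ge, ge]
        finite = np.isfinite(beta_ge[s:s + mm]) & (vm[s:s + mm] > 0) & (vr[s:s + mm] > 0)
        ok[s:s + mm] = finite
    return beta_ge, vm, vr, ok


# ----------------------------------------------------------------------
# Logistic family
# ----------------------------------------------------------------------
def fit_logistic_gxe(y, e, g, covariates=None, max_iter: int = 25,
                     tol: float = 1e-8, hc: str = "hc3") -> GxEFit:
    """Logistic regression by IRLS (statsmodels GLM) with Fisher/sandwich covariances.

    ``cov_model`` is the inverse Fisher information at the MLE (identical to
    the observed information under the canonical logit link); ``cov_robust``
    is A^-1 B A^-1 with B = sum_i x_i x_i' (y_i - mu_i)^2 / (1 - h_i)^2,
    where h_i is the weighted-design hat value (``hc="hc3"``, the default;
    ``hc="hc0"`` omits the leverage factor).  As in least squares, the
    leverage correction keeps the robust Wald test close to nominal at
    moderate n.  Separation or failure to reach score-norm ``tol`` yields a
    flagged non-converged fit.
    """
    import statsmodels.api as sm

    y = np.asarray(y, dtype=float)
    X, names, idx_g, idx_ge = _design(e, g, covariates, intercept=True)
    n, k = X.shape
    nan_cov = np.full((k, k), np.nan)
    fail = GxEFit(np.full(k, np.nan), names, nan_cov, nan_cov, False, n,
                  "logistic", idx_g=idx_g, idx_ge=idx_ge)
    if not np.isin(y, (0.0, 1.0)).all():
        raise DataError("logistic outcome must be 0/1")
    if y.min() == y.max():
        return fail                      # one outcome class only
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.GLM(y, X, family=sm.families.Binomial()).fit(
                maxiter=max_iter, tol=1e-10)
        beta = np.asarray(res.params, dtype=float)
        mu = np.asarray(res.predict(), dtype=float)
    except Exception:                    # separation, singular design, ...
        return fail
    W = mu * (1.0 - mu)
    score = X.T @ (y - mu)
    A = X.T @ (X * W[:, None])
    try:
        Ainv = np.linalg.inv(A)
    except np.linalg.LinAlgError:
        return fail
    if not np.isfinite(beta).all() or np.linalg.norm(score) > tol:
        return fail
    # perfect separation drives mu to the observed y everywhere while the
    # score still vanishes; flag it rather than report divergent estimates
    if np.abs(y - mu).max() < 1e-6 or np.abs(X @ beta).max() > 30.0:
        return fail
    r2 = (y - mu) ** 2
    if hc == "hc3":
        hat = np.einsum("ij,jk,ik->i", X, Ainv, X) * W
        r2 = r2 / (1.0 - np.minimum(hat, 1.0 - 1e-12)) ** 2
    elif hc != "hc0":
        raise ConfigError(f"logistic sandwich flavor must be 'hc0' or 'hc3', "
                          f"got {hc!r}")
    B = X.T @ (X * r2[:, None])
    cov_robust = Ainv @ B @ Ainv
    with np.errstate(divide="ignore"):
        ll = float(np.sum(y * np.log(mu) + (1 - y) * np.log1p(-mu)))
    return GxEFit(beta, names, Ainv, cov_robust, True, n, "logistic",
                  loglik=ll, idx_g=idx_g, idx_ge=idx_ge)


# ----------------------------------------------------------------------
# Cox family
# ----------------------------------------------------------------------
def fit_cox_gxe(time, status, e, g, covariates=None, max_iter: int = 25,
                tol: float = 1e-8, _cox_data: CoxData | None = None) -> GxEFit:
    """Cox proportional hazards for the interaction model (no intercept).

    Maximizes the Breslow partial likelihood by Newton-Raphson;
    ``cov_model`` is the inverse observed information and ``cov_robust`` the
    Lin-Wei sandwich I^-1 (sum_i s_i s_i') I^-1 built from per-subject
    score residuals.
    """
    time = np.asarray(time, dtype=float)
    status = np.asarray(status)
    if (time <= 0).any():
        raise DataError("survival times must be strictly positive")
    if status.sum() < 1:
        raise DataError("need at least one event")
    X, names, idx_g, idx_ge = _design(e, g, covariates, intercept=False)
    cd = _cox_data if _cox_data is not None else CoxData.from_arrays(time, status)
    beta, cov_model, cov_robust, converged, ll = cox_newton(
        cd, X, max_iter=max_iter, tol=tol)
    return GxEFit(beta, names, cov_model, cov_robust, converged, len(time),
                  "survival", loglik=ll, idx_g=idx_g, idx_ge=idx_ge)


# ----------------------------------------------------------------------
# Tests
# ----------------------------------------------------------------------
def wald_test(fit: GxEFit, se_flavor: str = "robust") -> TestResult:
    """1-df Wald test of the GxE interaction: (beta_GE / SE)^2 ~ chi^2_1."""
    if not fit.converged:
        raise GxescanError("cannot test a non-converged fit")
    se = fit.se(se_flavor)
    if se == 0.0 or not np.isfinite(se):
        return TestResult(np.nan, 1, np.nan, se_flavor, "wald")
    stat = (fit.beta_ge / se) ** 2
    p = float(max(stats.chi2.sf(stat, 1), _P_FLOOR))
    return TestResult(float(stat), 1, p, se_flavor, "wald")


def lrt_test(fit_full: GxEFit, fit_null: GxEFit) -> TestResult:
    """Likelihood-ratio test of nested fits (linear and logistic families)."""
    if fit_full.family == "survival" or fit_null.family == "survival":
        raise NotSupportedError("likelihood-ratio test is defined for the "
                                "linear and logistic families here")
    if fit_full.family != fit_null.family or fit_full.n_used != fit_null.n_used:
        raise GxescanError("LRT needs nested fits on identical subjects")
    df = len(fit_full.coefficients) - len(fit_null.coefficients)
    if df <= 0:
        raise GxescanError("fit_full must have more parameters than fit_null")
    stat = max(2.0 * (fit_full.loglik - fit_null.loglik), 0.0)
    p = float(max(stats.chi2.sf(stat, df), _P_FLOOR))
    return TestResult(float(stat), df, p, None, "lrt")


def joint_wald_test(fit: GxEFit, se_flavor: str = "robust") -> TestResult:
    """2-df Wald test of (beta_G, beta_GE) jointly, using the chosen covariance."""
    if not fit.converged:
        raise GxescanError("cannot test a non-converged fit")
    if fit.idx_g is None or fit.idx_ge is None:
        raise GxescanError("fit has no genotype terms")
    idx = [fit.idx_g, fit.idx_ge]
    b = fit.coefficients[idx]
    V = fit._cov(se_flavor)[np.ix_(idx, idx)]
    try:
        stat = float(b @ np.linalg.solve(V, b))
    except np.linalg.LinAlgError:
        raise GxescanError("(G, GxE) covariance block is singular")
    p = float(max(stats.chi2.sf(stat, 2), _P_FLOOR))
    return TestResult(stat, 2, p, se_flavor, "joint_wald")


# ----------------------------------------------------------------------
# Genome scan
# ----------------------------------------------------------------------
def _minor_allele_count(g: np.ndarray) -> float:
    g = g[~np.isnan(g)]
    total = g.sum()
    return float(min(total, 2 * len(g) - total))


def genome_scan(cohort: Cohort, covariates=None, hc: str = DEFAULT_HC,
                mac_min: int = 5, interact_covariates: bool = False,
                scenario: str = "", seed: int | None = None) -> ScanResult:
    """Fit the interaction model at every locus and tabulate both SE flavors.

    ``covariates`` (e.g. principal-component scores, shape n x q) enter every
    per-locus model as main effects; with ``interact_covariates=True`` their
    products with the exposure are added as well, which is the full
    adjustment when ancestry modifies the exposure effect.  Loci with
    minor-allele count below ``mac_min`` are flagged ``low_mac``; fits that
    fail are flagged ``not_converged``; both are excluded from lambda.
    """
    cohort.validate()
    family = cohort.family
    e = cohort.exposure
    G = cohort.genotypes
    n, m = G.shape

    C = None
    if covariates is not None:
        C = np.atleast_2d(np.asarray(covariates, dtype=float))
        if C.shape[0] != n:
            C = C.T
        if interact_covariates:
            C = np.column_stack([C, C * e[:, None]])

    mac = np.array([_minor_allele_count(G[:, j]) for j in range(m)])
    usable = mac >= mac_min
    has_missing = bool(np.isnan(G).any())

    beta_ge = np.full(m, np.nan)
    vm = np.full(m, np.nan)
    vr = np.full(m, np.nan)
    okfit = np.zeros(m, dtype=bool)
    n_used = np.full(m, n, dtype=int)

    def _record(j: int, fit: GxEFit):
        n_used[j] = fit.n_used
        if fit.converged:
            v_m = fit.cov_model[fit.idx_ge, fit.idx_ge]
            v_r = fit.cov_robust[fit.idx_ge, fit.idx_ge]
            if np.isfinite(v_m) and np.isfinite(v_r) and v_m > 0 and v_r > 0:
                beta_ge[j] = fit.beta_ge
                vm[j] = v_m
                vr[j] = v_r
                okfit[j] = True

    if family == "linear" and not has_missing:
        idx = np.where(usable)[0]
        if idx.size:
            b, v1, v2, ok = _linear_scan_batch(cohort.phenotype, e, G[:, idx],
                                               covariates=C, hc=hc)
            beta_ge[idx] = b
            vm[idx] = v1
            vr[idx] = v2
            okfit[idx] = ok
    else:
        cd = None
        if family == "survival" and not has_missing:
            cd = CoxData.from_arrays(cohort.time, cohort.status)
        for j in np.where(usable)[0]:
            g = G[:, j]
            mask = ~np.isnan(g)
            if family == "linear":
                fit = fit_linear_gxe(cohort.phenotype[mask], e[mask], g[mask],
                                     None if C is None else C[mask], hc=hc)
            elif family == "logistic":
                y = cohort.phenotype[mask]
                if y.min() == y.max():
                    n_used[j] = int(mask.sum())
                    continue
                fit = fit_logistic_gxe(y, e[mask], g[mask],
                                       None if C is None else C[mask],
                                       hc=hc if hc in ("hc0", "hc3") else "hc3")
            elif family == "survival":
                if mask.all() and cd is not None:
                    fit = fit_cox_gxe(cohort.time, cohort.status, e, g, C,
                                      _cox_data=cd)
                else:
                    fit = fit_cox_gxe(cohort.time[mask], cohort.status[mask],
                                      e[mask], g[mask],
                                      None if C is None else C[mask])
            else:
                raise ConfigError(f"unknown family {family!r}")
            _record(j, fit)

    status = np.where(~usable, STATUS_LOW_MAC,
                      np.where(okfit, STATUS_OK, STATUS_NOT_CONVERGED))
    se_m = np.sqrt(vm)
    se_r = np.sqrt(vr)
    with np.errstate(invalid="ignore", divide="ignore"):
        chi_m = beta_ge ** 2 / vm
        chi_r = beta_ge ** 2 / vr
    p_m = np.maximum(stats.chi2.sf(chi_m, 1), _P_FLOOR)
    p_r = np.maximum(stats.chi2.sf(chi_r, 1), _P_FLOOR)

    table = pd.DataFrame({
        "locus_id": cohort.locus_ids,
        "maf": cohort.maf,
        "n_used": n_used,
        "beta_gxe": beta_ge,
        "se_model": se_m,
        "se_robust": se_r,
        "chi2_model": chi_m,
        "chi2_robust": chi_r,
        "p_model": p_m,
        "p_robust": p_r,
        "status_code": status,
    })[RESULT_COLUMNS]
    n_bad = int((status != STATUS_OK).sum())
    logger.info("genome_scan: family=%s loci=%d fitted_ok=%d excluded=%d "
                "(low_mac=%d, not_converged=%d)", family, m, m - n_bad, n_bad,
                int((status == STATUS_LOW_MAC).sum()),
                int((status == STATUS_NOT_CONVERGED).sum()))
    return ScanResult(table=table, family=family, n_subjects=n,
                      scenario=scenario, seed=seed)
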