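"""Variance-decomposition experiments for the interaction estimator.

The genomic-control numerator is an *empirical variance across loci* of the
interaction coefficient — variability of beta_GE with the outcome Y and
exposure E held fixed while the genotype G changes from locus to locus.
Model-based standard errors instead estimate variability over Y with (E, G)
fixed.  By the law of total variance,

    Var(beta_GE) = Var_{Y,E}( E[beta_GE | Y, E] ) + E_{Y,E}( Var(beta_GE | Y, E) )

and the analogous split conditioning on (G, E).  When the exposure-outcome
mean model is correct, the first ("between-instance") term of the (Y,E)
split is approximately zero, so lambda built from either SE flavor is
calibrated; under mis-specification the (G,E)-conditional mean of beta_GE
varies from instance to instance and the model-based split acquires a
non-negligible first term — the mechanism behind spurious QQ-plot
inflation.  This module measures all of these quantities by direct
simulation with different variables held fixed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import ScenarioConfig
from .errors import ConfigError, NotSupportedError
from .regress import DEFAULT_HC, _hc_weights
from .sim import simulate_cohort, simulate_exposure, simulate_phenotype

__all__ = ["DecompResult", "run_decomposition", "between_term_ratio",
           "lambda_variance_ratio"]


@dataclass
class DecompResult:
    """Empirical variances of beta_GE under the three randomization regimes."""

    var_all_random: float        # Y, E, G all redrawn each replicate
    var_G_random: float          # mean within-(Y,E) variance, G redrawn (QQ/lambda view)
    var_Y_random: float          # mean within-(G,E) variance, Y redrawn (model-based view)
    mean_cov_model: float        # mean model-based variance estimate (all-random arm)
    mean_cov_robust: float       # mean sandwich variance estimate (all-random arm)
    between_term: float          # Var over (Y,E) instances of E[beta_GE | Y,E]
    between_term_ge: float       # Var over (G,E) instances of E[beta_GE | G,E]
    replicates: dict = field(default_factory=dict)
    draws: dict = field(default_factory=dict)   # per-arm beta_GE draws

    def law_of_total_variance_gap(self) -> float:
        """|var_all - (between + within)| for the (Y,E) split."""
        return abs(self.var_all_random - (self.between_term + self.var_G_random))


def _draw_genotype(rng, n, size, coding: str, freq: float):
    if coding == "binary":
        return rng.binomial(1, freq, size=(size, n)).astype(float)
    if coding == "additive":
        return rng.binomial(2, freq, size=(size, n)).astype(float)
    raise ConfigError(f"unknown genotype coding {coding!r}")


def _batch_ols_ge(y_batch: np.ndarray, e_batch: np.ndarray, g_batch: np.ndarray,
                  hc: str = DEFAULT_HC, want_var: bool = False):
    """beta_GE (and optionally both variance estimates) for a batch of
    (Y, E, G) replicates; design is (1, E, G, GxE) per replicate."""
    R, n = y_batch.shape
    X = np.empty((R, n, 4))
    X[:, :, 0] = 1.0
    X[:, :, 1] = e_batch
    X[:, :, 2] = g_batch
    X[:, :, 3] = g_batch * e_batch
    XtX = np.einsum("rnk,rnj->rkj", X, X)
    Xty = np.einsum("rnk,rn->rk", X, y_batch)
    XtXi = np.linalg.inv(XtX)
    beta = np.einsum("rkj,rj->rk", XtXi, Xty)
    if not want_var:
        return beta[:, 3], None, None
    r = y_batch - np.einsum("rnk,rk->rn", X, beta)
    sigma2 = (r ** 2).sum(axis=1) / (n - 4)
    h = np.einsum("rnk,rkj,rnj->rn", X, XtXi, X)
    w = _hc_weights(r ** 2, np.minimum(h, 1.0 - 1e-12), n, 4, hc)
    meat = np.einsum("rnk,rnj,rn->rkj", X, X, w)
    covr = XtXi @ meat @ XtXi
    return beta[:, 3], XtXi[:, 3, 3] * sigma2, covr[:, 3, 3]


def run_decomposition(config: ScenarioConfig, n_outer: int = 50,
                      n_inner: int = 200, genotype_coding: str = "binary",
                      genotype_freq: float = 0.3, hc: str = DEFAULT_HC,
                      seed: int | None = None) -> DecompResult:
    """Measure beta_GE variability with different variables held fixed.

    Three arms, all under the no-interaction null of the given (linear
    family) scenario, with a single genotype per replicate:

    * all random — n_outer * n_inner independent (E, Y, G) replicates;
    * G random   — n_outer fixed (Y, E) instances, n_inner genotype redraws
      each (the regime a QQ-plot/lambda actually displays);
    * Y random   — n_outer fixed (G, E) instances, n_inner outcome redraws
      each (the regime model-based standard errors describe).

    The genotype is a two-group indicator by default (``binary``);
    ``additive`` gives 0/1/2 coding.
    """
    config.validate()
    if config.family != "linear":
        raise NotSupportedError("the decomposition experiment is defined for "
                                "the linear family; other families are "
                                "covered by scan-level lambda")
    if n_outer < 2 or n_inner < 2:
        raise ConfigError("n_outer and n_inner must both be >= 2 (a single "
                          "inner replicate leaves the within-instance "
                          "variance undefined)")
    n = config.n_subjects
    rng = np.random.default_rng(config.seed if seed is None else seed)

    # --- arm 1: everything random -------------------------------------
    R = n_outer * n_inner
    draws_all = np.empty(R)
    cov_m = np.empty(R)
    cov_r = np.empty(R)
    chunk = max(1, int(2e6 // (4 * n)))
    for s in range(0, R, chunk):
        r = min(chunk, R - s)
        e = np.vstack([simulate_exposure(n, rng, config.exposure_mean,
                                         config.exposure_sd) for _ in range(r)])
        y = np.vstack([simulate_phenotype(e[i], config, rng=rng)
                       for i in range(r)])
        g = _draw_genotype(rng, n, r, genotype_coding, genotype_freq)
        b, vm, vr = _batch_ols_ge(y, e, g, hc=hc, want_var=True)
        draws_all[s:s + r] = b
        cov_m[s:s + r] = vm
        cov_r[s:s + r] = vr
    var_all = float(np.var(draws_all, ddof=1))

    # --- arm 2: (Y, E) fixed per instance, G redrawn -------------------
    within_G = np.empty(n_outer)
    means_G = np.empty(n_outer)
    draws_G = np.empty((n_outer, n_inner))
    for i in range(n_outer):
        e1 = simulate_exposure(n, rng, config.exposure_mean, config.exposure_sd)
        y1 = simulate_phenotype(e1, config, rng=rng)
        g = _draw_genotype(rng, n, n_inner, genotype_coding, genotype_freq)
        b, _, _ = _batch_ols_ge(np.tile(y1, (n_inner, 1)),
                                np.tile(e1, (n_inner, 1)), g, hc=hc)
        draws_G[i] = b
        within_G[i] = np.var(b, ddof=1)
        means_G[i] = b.mean()
    var_G = float(within_G.mean())
    between = float(np.var(means_G, ddof=1))

    # --- arm 3: (G, E) fixed per instance, Y redrawn -------------------
    within_Y = np.empty(n_outer)
    means_Y = np.empty(n_outer)
    draws_Y = np.empty((n_outer, n_inner))
    for i in range(n_outer):
        e1 = simulate_exposure(n, rng, config.exposure_mean, config.exposure_sd)
        g1 = _draw_genotype(rng, n, 1, genotype_coding, genotype_freq)[0]
        y = np.vstack([simulate_phenotype(e1, config, rng=rng)
                       for _ in range(n_inner)])
        b, _, _ = _batch_ols_ge(y, np.tile(e1, (n_inner, 1)),
                                np.tile(g1, (n_inner, 1)), hc=hc)
        draws_Y[i] = b
        within_Y[i] = np.var(b, ddof=1)
        means_Y[i] = b.mean()
    var_Y = float(within_Y.mean())
    between_ge = float(np.var(means_Y, ddof=1))

    return DecompResult(
        var_all_random=var_all, var_G_random=var_G, var_Y_random=var_Y,
        mean_cov_model=float(cov_m.mean()), mean_cov_robust=float(cov_r.mean()),
        between_term=between, between_term_ge=between_ge,
        replicates={"all_random": R, "G_random": (n_outer, n_inner),
                    "Y_random": (n_outer, n_inner)},
        draws={"all_random": draws_all, "G_random": draws_G, "Y_random": draws_Y},
    )


def between_term_ratio(config: ScenarioConfig, held: str = "y_e",
                       n_outer: int = 50, n_inner: int = 200,
                       seed: int | None = None, **kwargs) -> float:
    """Normalized first term of the law-of-total-variance split.

    ``held="y_e"`` returns Var_{Y,E}(E[beta_GE|Y,E]) / Var(beta_GE) — the
    term that is approximately zero for correctly specified (and, it turns
    out, even mis-specified) least-squares interaction scans.  ``held="g_e"``
    returns the analogous ratio conditioning on (G, E), which is the term
    model-based standard errors ignore; it is only negligible when the mean
    model is correct.
    """
    res = run_decomposition(config, n_outer=n_outer, n_inner=n_inner,
                            seed=seed, **kwargs)
    if held == "y_e":
        return res.between_term / res.var_all_random
    if held == "g_e":
        return res.between_term_ge / res.var_all_random
    raise ConfigError("held must be 'y_e' or 'g_e'")


def lambda_variance_ratio(config: ScenarioConfig,
                          hc: str = DEFAULT_HC) -> tuple[float, float]:
    """Population quantities lambda estimates, from one null genome scan.

    Returns (empirical variance of beta_GE across loci / mean model-based
    variance estimate, same / mean robust variance estimate).  The first
    ratio exceeds 1 under mean-model mis-specification even with no
    confounding; the second stays near 1.
    """
    from .regress import genome_scan

    config.validate()
    if config.family != "linear":
        raise NotSupportedError("lambda_variance_ratio is defined for the "
                                "linear family")
    cohort = simulate_cohort(config)
    scan = genome_scan(cohort, hc=hc, seed=config.seed)
    ok = scan.converged()
    emp = float(np.var(ok.beta_gxe.to_numpy(), ddof=1))
    return (emp / float((ok.se_model.to_numpy() ** 2).mean()),
            emp / float((ok.se_robust.to_numpy() ** 2).mean()))
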