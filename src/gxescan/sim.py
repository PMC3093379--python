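"""Synthetic GxE GWAS cohorts.

The simulator produces cohorts in which genotype is *never* used when
generating the phenotype, so the no-interaction null holds at every locus by
construction.  Inflation of interaction test statistics in scans of these
cohorts is therefore entirely an artifact of variance estimation (or, in the
stratified scenarios, of confounding by substructure) and not of true
signal.

Components:

* minor allele frequencies from a truncated/floored beta law;
* genotypes Binomial(2, MAF), i.e. biallelic loci in Hardy-Weinberg
  equilibrium, coded as minor-allele counts 0/1/2;
* optional two-or-more-subpopulation structure with per-locus subpopulation
  MAFs from the Balding-Nichols beta model at a given Wright's F_ST;
* a normally distributed environmental exposure;
* phenotypes from a catalogue of correctly specified and mis-specified
  exposure-phenotype models (linear, quadratic, exponential mean models;
  constant or exposure-dependent residual variance; logit-quadratic binary
  outcomes; quadratic-log-hazard exponential survival times with optional
  censoring at the median survival time).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .config import Censoring, MafLaw, ScenarioConfig
from .errors import ConfigError, DataError

logger = logging.getLogger(__name__)


# ----------------------------------------------------------------------
# Cohort container
# ----------------------------------------------------------------------
@dataclass
class Cohort:
    """One simulated (or loaded) dataset.

    ``phenotype`` holds the continuous or 0/1 outcome for the linear and
    logistic families; the survival family uses ``time`` and ``status``
    instead (status 1 = event observed, 0 = censored).
    """

    exposure: np.ndarray
    genotypes: np.ndarray            # n x m, entries in {0,1,2} (NaN allowed for loaded data)
    maf: np.ndarray                  # length m
    family: str = "linear"
    phenotype: np.ndarray | None = None
    time: np.ndarray | None = None
    status: np.ndarray | None = None
    subpop: np.ndarray | None = None
    locus_ids: list[str] = field(default_factory=list)
    sample_ids: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.exposure = np.asarray(self.exposure, dtype=float)
        self.genotypes = np.asarray(self.genotypes, dtype=float)
        self.maf = np.asarray(self.maf, dtype=float)
        if not self.locus_ids:
            self.locus_ids = [f"locus{j + 1}" for j in range(self.n_loci)]
        if not self.sample_ids:
            self.sample_ids = [f"s{i + 1}" for i in range(self.n_subjects)]

    @property
    def n_subjects(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_loci(self) -> int:
        return self.genotypes.shape[1]

    def validate(self) -> "Cohort":
        n, m = self.genotypes.shape
        if self.exposure.shape != (n,):
            raise DataError("exposure length does not match genotype rows")
        if self.maf.shape != (m,):
            raise DataError("maf length does not match genotype columns")
        g = self.genotypes[~np.isnan(self.genotypes)]
        if g.size and not np.isin(g, (0.0, 1.0, 2.0)).all():
            raise DataError("genotype entries must be 0, 1 or 2")
        if self.family == "survival":
            if self.time is None or self.status is None:
                raise DataError("survival cohort needs time and status")
            if self.time.shape != (n,) or self.status.shape != (n,):
                raise DataError("time/status length mismatch")
            if (self.time <= 0).any():
                raise DataError("survival times must be strictly positive")
            if not np.isin(self.status, (0, 1)).all():
                raise DataError("status must be 0/1")
        else:
            if self.phenotype is None:
                raise DataError(f"{self.family} cohort needs a phenotype vector")
            if self.phenotype.shape != (n,):
                raise DataError("phenotype length mismatch")
            if self.family == "logistic" and not np.isin(self.phenotype, (0, 1)).all():
                raise DataError("logistic phenotype must be 0/1")
        if self.subpop is not None and self.subpop.shape != (n,):
            raise DataError("subpop length mismatch")
        if len(self.locus_ids) != m or len(self.sample_ids) != n:
            raise DataError("id lists do not match matrix dimensions")
        return self


# ----------------------------------------------------------------------
# Elementary draws
# ----------------------------------------------------------------------
def draw_maf(m: int, law: MafLaw | None = None,
             rng: np.random.Generator | None = None) -> np.ndarray:
    """Draw ``m`` minor allele frequencies from the truncated/floored beta law.

    Rejection sampling: beta(alpha, beta) draws outside [floor, truncation]
    are discarded, which realises the beta density restricted to that
    interval exactly.
    """
    law = law or MafLaw()
    law.validate()
    if m < 0:
        raise ConfigError("m must be non-negative")
    rng = rng if rng is not None else np.random.default_rng()
    out = np.empty(m)
    have = 0
    while have < m:
        block = max(m - have, 1000)
        d = rng.beta(law.alpha, law.beta, size=2 * block)
        d = d[(d >= law.floor) & (d <= law.truncation)]
        take = min(len(d), m - have)
        out[have:have + take] = d[:take]
        have += take
    return out


def draw_genotypes(maf: np.ndarray, n: int,
                   rng: np.random.Generator | None = None) -> np.ndarray:
    """Hardy-Weinberg genotypes: column j is i.i.d. Binomial(2, maf_j)."""
    maf = np.atleast_1d(np.asarray(maf, dtype=float))
    if ((maf < 0) | (maf > 1)).any():
        raise ConfigError("maf values must lie in [0, 1]")
    if n < 1:
        raise ConfigError("n must be >= 1")
    rng = rng if rng is not None else np.random.default_rng()
    return rng.binomial(2, maf[None, :], size=(n, len(maf))).astype(np.int8)


def draw_subpop_mafs(central_maf: float, fst: float, n_subpops: int = 2,
                     rng: np.random.Generator | None = None) -> np.ndarray:
    """Balding-Nichols subpopulation MAFs around a central frequency.

    Each subpopulation's MAF is an independent draw from
    Beta(p(1-F)/F, (1-p)(1-F)/F), which has mean p and variance F p(1-p).
    ``fst = 0`` is the no-drift limit and returns the central MAF replicated.
    """
    if not (0.0 < central_maf < 1.0):
        raise ConfigError("central_maf must be in (0, 1)")
    if not (0.0 <= fst < 1.0):
        raise ConfigError("fst must be in [0, 1)")
    if fst == 0.0:
        logger.info("draw_subpop_mafs: fst=0, returning central MAF replicated")
        return np.full(n_subpops, central_maf)
    rng = rng if rng is not None else np.random.default_rng()
    a = central_maf * (1.0 - fst) / fst
    b = (1.0 - central_maf) * (1.0 - fst) / fst
    return rng.beta(a, b, size=n_subpops)


def _draw_subpop_maf_matrix(central: np.ndarray, fst: float, n_subpops: int,
                            rng: np.random.Generator) -> np.ndarray:
    """Vectorized Balding-Nichols draw: returns (n_subpops, m) matrix."""
    if fst == 0.0:
        return np.tile(central, (n_subpops, 1))
    a = central * (1.0 - fst) / fst
    b = (1.0 - central) * (1.0 - fst) / fst
    return rng.beta(a[None, :], b[None, :], size=(n_subpops, len(central)))


def simulate_exposure(n: int, rng: np.random.Generator | None = None,
                      mean: float = 0.0, sd: float = 1.0) -> np.ndarray:
    """Normally distributed environmental exposure, standard Normal by default."""
    if n < 0:
        raise ConfigError("n must be non-negative")
    rng = rng if rng is not None else np.random.default_rng()
    return rng.normal(mean, sd, size=n)


# ----------------------------------------------------------------------
# Phenotype generation
# ----------------------------------------------------------------------
def _linear_coef_vector(config: ScenarioConfig, n: int,
                        subpop: np.ndarray | None) -> np.ndarray:
    """Per-subject linear exposure coefficient (differs by subpopulation
    when stratification is active; quadratic term stays shared)."""
    c = config.coefficients
    if config.stratification is not None and subpop is not None:
        coefs = np.asarray(config.stratification.per_subpop_linear_coef, dtype=float)
        return coefs[subpop]
    return np.full(n, c.linear)


def simulate_phenotype(exposure: np.ndarray, config: ScenarioConfig,
                       subpop: np.ndarray | None = None,
                       rng: np.random.Generator | None = None):
    """Generate the phenotype for one cohort; genotypes never enter.

    Returns an array ``y`` for the linear/logistic families and a
    ``(time, status)`` pair for the survival family (censoring applied when
    enabled in the config).
    """
    config.validate()
    rng = rng if rng is not None else np.random.default_rng()
    e = np.asarray(exposure, dtype=float)
    n = len(e)
    c = config.coefficients
    b = _linear_coef_vector(config, n, subpop)

    if config.family == "linear":
        if config.mean_model == "linear":
            mu = c.intercept + b * e
        elif config.mean_model == "quadratic":
            mu = c.intercept + b * e + c.quadratic * e ** 2
        else:  # exponential: amplitude lives in the intercept slot
            mu = c.intercept * np.exp(b * e)
        sd = c.noise_sd * (1.0 + np.abs(e)) \
            if config.variance_model == "exposure_dependent" else c.noise_sd
        return mu + rng.normal(0.0, 1.0, size=n) * sd

    if config.family == "logistic":
        from scipy.special import expit
        p = expit(c.intercept + b * e + c.quadratic * e ** 2)
        return rng.binomial(1, p).astype(np.int8)

    # survival: Exponential(rate = exp(intercept + b E + c E^2))
    rate = np.exp(c.intercept + b * e + c.quadratic * e ** 2)
    times = rng.exponential(1.0 / rate)
    if config.censoring.enabled:
        return apply_censoring(times, config.censoring, rng=rng)
    return times, np.ones(n, dtype=np.int8)


def apply_censoring(times: np.ndarray, censoring: Censoring | None = None,
                    rng: np.random.Generator | None = None,
                    cutoff: float | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Censor event times, targeting a given censored fraction.

    ``fixed_cutoff`` (default): administrative cutoff at the empirical
    (1 - target_fraction) quantile of the event times (the median survival
    time when the target is 0.5), or at an explicit ``cutoff``.
    ``uniform``: independent Uniform(0, 2 * median) censoring times.
    """
    censoring = censoring or Censoring(enabled=True)
    censoring.validate()
    times = np.asarray(times, dtype=float)
    if (times <= 0).any():
        raise DataError("event times must be strictly positive")
    if censoring.mode == "uniform":
        rng = rng if rng is not None else np.random.default_rng()
        cens = rng.uniform(0.0, 2.0 * np.median(times), size=len(times))
    else:
        if cutoff is None:
            cutoff = float(np.quantile(times, 1.0 - censoring.target_fraction))
        cens = np.full(len(times), cutoff)
    status = (times <= cens).astype(np.int8)
    observed = np.minimum(times, cens)
    return observed, status


# ----------------------------------------------------------------------
# Whole-cohort simulation
# ----------------------------------------------------------------------
def simulate_cohort(config: ScenarioConfig) -> Cohort:
    """Simulate a full cohort from a scenario config; reproducible from seed.

    Draw order (fixed for reproducibility): subpopulation labels, central
    MAFs, subpopulation MAFs, genotypes, exposure, phenotype.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n, m = config.n_subjects, config.n_loci

    subpop = None
    if config.stratification is not None:
        strat = config.stratification
        fracs = np.asarray(strat.subpop_fractions)
        subpop = rng.choice(len(fracs), size=n, p=fracs)
    central = draw_maf(m, config.maf_law, rng)
    if config.stratification is not None:
        sub_mafs = _draw_subpop_maf_matrix(central, strat.fst,
                                           strat.n_subpops, rng)
        per_subject_p = sub_mafs[subpop, :]          # n x m
        genotypes = rng.binomial(2, per_subject_p).astype(np.int8)
    else:
        genotypes = draw_genotypes(central, n, rng)

    exposure = simulate_exposure(n, rng, config.exposure_mean, config.exposure_sd)
    pheno = simulate_phenotype(exposure, config, subpop=subpop, rng=rng)

    kwargs: dict = {"family": config.family}
    if config.family == "survival":
        kwargs["time"], kwargs["status"] = pheno
        kwargs["time"] = np.asarray(kwargs["time"], dtype=float)
        kwargs["status"] = np.asarray(kwargs["status"], dtype=np.int8)
    else:
        kwargs["phenotype"] = np.asarray(pheno, dtype=float)
    return Cohort(exposure=exposure, genotypes=genotypes, maf=central,
                  subpop=subpop, **kwargs).validate()
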