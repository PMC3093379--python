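"""Scenario configuration for simulated GxE GWAS cohorts.

A :class:`ScenarioConfig` is the complete recipe for one simulation scenario:
the regression family, the true exposure-phenotype mean model (possibly
mis-specified relative to the fitted linear interaction model), the residual
variance model, sample sizes, the minor-allele-frequency law, optional
two-or-more-subpopulation stratification, censoring for survival outcomes,
and the seed.  Configs round-trip losslessly through YAML; unknown keys are
rejected so that typos cannot silently change a scenario.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from .errors import ConfigError

FAMILIES = ("linear", "logistic", "survival")
MEAN_MODELS = ("linear", "quadratic", "exponential", "logit_quadratic",
               "loghazard_quadratic")
VARIANCE_MODELS = ("constant", "exposure_dependent")

#: mean models that make sense for each regression family
FAMILY_MEAN_MODELS = {
    "linear": ("linear", "quadratic", "exponential"),
    "logistic": ("logit_quadratic",),
    "survival": ("loghazard_quadratic",),
}


@dataclass
class MafLaw:
    """Beta law for minor allele frequencies, truncated and floored.

    MAFs are drawn i.i.d. from Beta(alpha, beta) restricted (by rejection)
    to the interval [floor, truncation].  The defaults give the classic
    U-shaped beta(.5,.5) allele-frequency spectrum truncated at 1/2 with
    rare alleles below 2% removed.
    """

    alpha: float = 0.5
    beta: float = 0.5
    truncation: float = 0.5
    floor: float = 0.02

    def validate(self) -> None:
        if not (self.alpha > 0 and self.beta > 0):
            raise ConfigError("maf_law: alpha and beta must be positive")
        if not (0.0 <= self.floor < self.truncation <= 0.5):
            raise ConfigError(
                "maf_law: need floor < truncation <= 0.5, got "
                f"floor={self.floor}, truncation={self.truncation}")


@dataclass
class Stratification:
    """Two-or-more-subpopulation structure in the Balding-Nichols sense.

    Each locus has a central MAF p; subpopulation MAFs are independent draws
    from Beta(p(1-F)/F, (1-p)(1-F)/F) with F = Wright's fixation index
    ``fst``.  Confounding of the interaction test is induced by letting the
    linear exposure-phenotype coefficient differ between subpopulations
    (``per_subpop_linear_coef``) while the quadratic term is shared.
    """

    fst: float = 0.01
    subpop_fractions: tuple[float, ...] = (0.2, 0.8)
    per_subpop_linear_coef: tuple[float, ...] = (1.2, 1.0)

    def validate(self) -> None:
        if not (0.0 <= self.fst < 1.0):
            raise ConfigError(f"stratification: fst must be in [0,1), got {self.fst}")
        fr = np.asarray(self.subpop_fractions, dtype=float)
        if fr.ndim != 1 or len(fr) < 2 or (fr <= 0).any():
            raise ConfigError("stratification: need >= 2 positive subpop_fractions")
        if abs(fr.sum() - 1.0) > 1e-12:
            raise ConfigError(
                f"stratification: subpop_fractions must sum to 1, got {fr.sum()!r}")
        if len(self.per_subpop_linear_coef) != len(fr):
            raise ConfigError(
                "stratification: per_subpop_linear_coef length must equal the "
                "number of subpopulations")

    @property
    def n_subpops(self) -> int:
        return len(self.subpop_fractions)


@dataclass
class Coefficients:
    """Generating coefficients of the exposure-phenotype relationship.

    Interpretation depends on the mean model:

    * ``linear``:              mu = intercept + linear*E
    * ``quadratic``:           mu = intercept + linear*E + quadratic*E^2
    * ``exponential``:         mu = intercept * exp(linear*E)  (amplitude in
      the intercept slot)
    * ``logit_quadratic``:     logit P(Y=1) = intercept + linear*E + quadratic*E^2
    * ``loghazard_quadratic``: log rate     = intercept + linear*E + quadratic*E^2

    ``noise_sd`` is the residual standard deviation for the linear family;
    under the ``exposure_dependent`` variance model the residual sd is
    noise_sd * (1 + |E|).
    """

    intercept: float = 0.0
    linear: float = 1.0
    quadratic: float = 0.0
    noise_sd: float = 1.0

    def validate(self) -> None:
        if self.noise_sd < 0:
            raise ConfigError(f"coefficients: noise_sd must be >= 0, got {self.noise_sd}")


@dataclass
class Censoring:
    """Censoring of survival outcomes.

    ``fixed_cutoff`` censors administratively at the empirical
    (1 - target_fraction) quantile of the event times, so a target of 0.5
    censors at the median survival time.  ``uniform`` draws per-subject
    censoring times from Uniform(0, 2 * median event time).
    """

    enabled: bool = False
    target_fraction: float = 0.5
    mode: str = "fixed_cutoff"

    def validate(self) -> None:
        if not (0.0 < self.target_fraction < 1.0):
            raise ConfigError("censoring: target_fraction must be in (0,1)")
        if self.mode not in ("fixed_cutoff", "uniform"):
            raise ConfigError(f"censoring: unknown mode {self.mode!r}")


@dataclass
class ScenarioConfig:
    """Full recipe for one simulation scenario."""

    family: str = "linear"
    mean_model: str = "linear"
    variance_model: str = "constant"
    n_subjects: int = 1000
    n_loci: int = 10000
    maf_law: MafLaw = field(default_factory=MafLaw)
    stratification: Stratification | None = None
    coefficients: Coefficients = field(default_factory=Coefficients)
    censoring: Censoring = field(default_factory=Censoring)
    exposure_mean: float = 0.0
    exposure_sd: float = 1.0
    seed: int = 0

    def validate(self) -> "ScenarioConfig":
        if self.family not in FAMILIES:
            raise ConfigError(f"unknown family {self.family!r}")
        if self.mean_model not in MEAN_MODELS:
            raise ConfigError(f"unknown mean_model {self.mean_model!r}")
        if self.mean_model not in FAMILY_MEAN_MODELS[self.family]:
            raise ConfigError(
                f"mean_model {self.mean_model!r} is not defined for family "
                f"{self.family!r}; choose one of {FAMILY_MEAN_MODELS[self.family]}")
        if self.variance_model not in VARIANCE_MODELS:
            raise ConfigError(f"unknown variance_model {self.variance_model!r}")
        if self.variance_model == "exposure_dependent" and self.family != "linear":
            raise ConfigError("exposure_dependent variance is only defined for the "
                              "linear family")
        if self.n_subjects < 2:
            raise ConfigError("n_subjects must be >= 2")
        if self.n_loci < 1:
            raise ConfigError("n_loci must be >= 1")
        if self.exposure_sd <= 0:
            raise ConfigError("exposure_sd must be positive")
        if self.censoring.enabled and self.family != "survival":
            raise ConfigError("censoring applies to the survival family only")
        self.maf_law.validate()
        self.coefficients.validate()
        self.censoring.validate()
        if self.stratification is not None:
            self.stratification.validate()
        return self

    # ------------------------------------------------------------------
    # YAML round-trip
    # ------------------------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if self.stratification is not None:
            d["stratification"]["subpop_fractions"] = list(
                self.stratification.subpop_fractions)
            d["stratification"]["per_subpop_linear_coef"] = list(
                self.stratification.per_subpop_linear_coef)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ScenarioConfig":
        d = dict(d)
        top = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - top
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")

        def _sub(key: str, klass):
            if key not in d or d[key] is None:
                return None
            sub = dict(d[key])
            names = {f.name for f in dataclasses.fields(klass)}
            bad = set(sub) - names
            if bad:
                raise ConfigError(f"unknown keys in {key!r}: {sorted(bad)}")
            for name in ("subpop_fractions", "per_subpop_linear_coef"):
                if name in sub and sub[name] is not None:
                    sub[name] = tuple(float(v) for v in sub[name])
            return klass(**sub)

        kwargs = {k: v for k, v in d.items()
                  if k not in ("maf_law", "stratification", "coefficients", "censoring")}
        for key, klass in (("maf_law", MafLaw), ("coefficients", Coefficients),
                           ("censoring", Censoring)):
            sub = _sub(key, klass)
            if sub is not None:
                kwargs[key] = sub
        strat = _sub("stratification", Stratification)
        kwargs["stratification"] = strat
        return cls(**kwargs).validate()

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump(self.to_dict(), sort_keys=False, default_flow_style=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ScenarioConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if not isinstance(raw, dict):
            raise ConfigError(f"config file {path} is not a mapping")
        return cls.from_dict(raw)

    def replace(self, **kwargs) -> "ScenarioConfig":
        return dataclasses.replace(self, **kwargs).validate()
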