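"""Shipped scenario presets.

Each preset reproduces one figure-style scenario family at default sizes:

* ``fig1``         — correctly specified linear model (no inflation for
  either SE flavor);
* ``fig2a``        — quadratic mean model fitted as linear (model-based
  inflation, robust calibrated);
* ``fig2c``        — linear mean with exposure-dependent residual sd
  (heteroskedasticity; same qualitative picture);
* ``fig3``         — fig2a's mis-specification plus two-subpopulation
  structure at F_ST = 0.01 with subpopulation-specific exposure slopes
  (run with one PC as covariate);
* ``fig4_logistic`` — binary outcome, logit-quadratic in exposure;
* ``fig4_cox``      — exponential survival times, quadratic log hazard,
  half the cohort censored at the median survival time;
* ``fig5``          — the variance-decomposition experiment scenarios
  (correct linear and exponential mean models at n = 500).
"""

from __future__ import annotations

from .config import Censoring, Coefficients, ScenarioConfig, Stratification
from .errors import ConfigError


def _linear(**kw) -> ScenarioConfig:
    return ScenarioConfig(family="linear", **kw).validate()


def make_preset(name: str, seed: int = 0) -> dict:
    """Returns {"config": ScenarioConfig, "n_pcs": int, "decomp": bool}."""
    presets = {
        "fig1": dict(config=_linear(
            mean_model="linear",
            coefficients=Coefficients(intercept=0.0, linear=1.0, quadratic=0.0,
                                      noise_sd=1.0), seed=seed)),
        "fig2a": dict(config=_linear(
            mean_model="quadratic",
            coefficients=Coefficients(intercept=0.0, linear=1.0, quadratic=1.0,
                                      noise_sd=1.0), seed=seed)),
        "fig2c": dict(config=_linear(
            mean_model="linear", variance_model="exposure_dependent",
            coefficients=Coefficients(intercept=0.0, linear=1.0, quadratic=0.0,
                                      noise_sd=1.0), seed=seed)),
        "fig3": dict(config=_linear(
            mean_model="quadratic",
            stratification=Stratification(fst=0.01, subpop_fractions=(0.2, 0.8),
                                          per_subpop_linear_coef=(1.2, 1.0)),
            coefficients=Coefficients(intercept=0.0, linear=1.0, quadratic=0.5,
                                      noise_sd=1.0), seed=seed), n_pcs=1),
        "fig4_logistic": dict(config=ScenarioConfig(
            family="logistic", mean_model="logit_quadratic", n_loci=2000,
            coefficients=Coefficients(intercept=-1.0, linear=1.0, quadratic=0.5,
                                      noise_sd=1.0), seed=seed).validate()),
        "fig4_cox": dict(config=ScenarioConfig(
            family="survival", mean_model="loghazard_quadratic", n_loci=2000,
            coefficients=Coefficients(intercept=0.0, linear=1.0, quadratic=0.5,
                                      noise_sd=1.0),
            censoring=Censoring(enabled=True, target_fraction=0.5),
            seed=seed).validate()),
        "fig5": dict(config=_linear(
            mean_model="exponential", n_subjects=500, n_loci=1,
            coefficients=Coefficients(intercept=1.0, linear=1.0, quadratic=0.0,
                                      noise_sd=1.0), seed=seed), decomp=True),
    }
    if name not in presets:
        raise ConfigError(f"unknown preset {name!r}; available: {sorted(presets)}")
    out = {"n_pcs": 0, "decomp": False}
    out.update(presets[name])
    return out


PRESET_NAMES = ("fig1", "fig2a", "fig2c", "fig3", "fig4_logistic", "fig4_cox",
                "fig5")
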