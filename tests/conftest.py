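import numpy as np
import pytest

from gxescan import Censoring, Coefficients, ScenarioConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_linear_cohort():
    """Correct linear model, modest sizes, fixed seed."""
    cfg = ScenarioConfig(n_subjects=400, n_loci=300, seed=11)
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def linear_fixture_20():
    """Fixed 20-subject (y, e, g) triple for exact sandwich checks."""
    rng = np.random.default_rng(5)
    e = rng.normal(size=20)
    g = rng.binomial(2, 0.4, size=20).astype(float)
    y = 0.3 + e + 0.5 * g + rng.normal(size=20) * (1 + 0.5 * np.abs(e))
    return y, e, g


@pytest.fixture(scope="session")
def logistic_fixture_30():
    """Fixed 30-subject binary-outcome fixture (well separated from separation)."""
    rng = np.random.default_rng(7)
    e = rng.normal(size=30)
    g = rng.binomial(2, 0.4, size=30).astype(float)
    logit = 0.2 + 0.5 * e - 0.3 * g + 0.4 * g * e
    p = 1.0 / (1.0 + np.exp(-logit))
    y = rng.binomial(1, p).astype(float)
    return y, e, g


@pytest.fixture(scope="session")
def cox_fixture_30():
    """Fixed 30-subject survival fixture; matches the frozen R reference."""
    rng = np.random.default_rng(1)
    x = np.column_stack([rng.normal(size=30),
                         rng.binomial(1, 0.5, 30).astype(float)])
    t = rng.exponential(1, 30)
    status = (rng.random(30) < 0.7).astype(int)
    return t, status, x


@pytest.fixture(scope="session")
def survival_cohort_small():
    cfg = ScenarioConfig(family="survival", mean_model="loghazard_quadratic",
                         n_subjects=300, n_loci=100,
                         coefficients=Coefficients(0.0, 1.0, 0.5, 1.0),
                         censoring=Censoring(enabled=True), seed=13)
    return simulate_cohort(cfg)
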