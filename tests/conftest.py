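import numpy as np
import pytest

from regrowth import BurdenDistribution, GrowthLawParams, RegrowthModel


@pytest.fixture
def baseline_model():
    """Exponential-law model at the parameter-effect baseline."""
    return RegrowthModel(GrowthLawParams("exponential", 0.0015), eps_V=0.01, omega_d=0.056)


@pytest.fixture
def burden_dist():
    """Lognormal burden distribution: arithmetic mean 0.05 cc, sd 0.06 cc."""
    return BurdenDistribution("arithmetic", 0.05, 0.06)


@pytest.fixture
def growthlaw_models():
    """The three growth laws at equal rate, shared thresholds and capacity."""
    eps_V, omega_d, lam, K = 0.015, 0.056, 0.0009, 13.8
    return {
        "exponential": RegrowthModel(GrowthLawParams("exponential", lam), eps_V, omega_d),
        "logistic": RegrowthModel(GrowthLawParams("logistic", lam, K), eps_V, omega_d),
        "gompertz": RegrowthModel(GrowthLawParams("gompertz", lam, K), eps_V, omega_d),
    }


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)
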