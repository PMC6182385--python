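import numpy as np
import pytest

from frrf import (
    FlashletTrain,
    GeneratorConfig,
    PhotophysState,
    calibrate_dose,
    default_rlc_sequence,
    generate_experiment,
    pair_measurements,
)


@pytest.fixture
def dark_state() -> PhotophysState:
    return PhotophysState(
        F0=0.2, FM=1.0, sigma=400.0, rho=0.3,
        tau1=500.0, tau2=5000.0, alpha1=0.7, alpha2=0.3,
    )


@pytest.fixture
def train() -> FlashletTrain:
    return FlashletTrain(dose_per_flashlet=calibrate_dose(400.0, 30, 0.98))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def rlc_noiseless():
    """One noiseless synthetic RLC: (config, transients, truth points, train)."""
    cfg = GeneratorConfig(seed=0, noise_cv=0.0)
    transients, points, train = generate_experiment(cfg, default_rlc_sequence())
    return cfg, transients, points, train


@pytest.fixture(scope="session")
def rlc_table_noiseless(rlc_noiseless):
    cfg, transients, points, train = rlc_noiseless
    return pair_measurements(transients, train)


@pytest.fixture(scope="session")
def rlc_noisy():
    """One noisy synthetic RLC (cv = 1%) plus its fitted table."""
    cfg = GeneratorConfig(seed=7, noise_cv=0.01)
    transients, points, train = generate_experiment(cfg, default_rlc_sequence())
    table = pair_measurements(transients, train)
    return cfg, points, table
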