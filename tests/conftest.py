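import numpy as np
import pytest

from equatesim.population import (
    GeneratorConfig,
    calibrate_item_bank,
    generate_population,
)


@pytest.fixture(scope="session")
def default_config():
    return GeneratorConfig()


@pytest.fixture(scope="session")
def bank(default_config):
    return calibrate_item_bank(default_config)


@pytest.fixture(scope="session")
def population(bank, default_config):
    """Full-size synthetic population (8000 examinees, both forms)."""
    return generate_population(bank, default_config)


@pytest.fixture(scope="session")
def small_population(bank):
    """A 1200-examinee population for cheaper simulation tests."""
    cfg = GeneratorConfig(n=1200, seed=42)
    return generate_population(bank, cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
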