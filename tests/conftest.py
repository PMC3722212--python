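import numpy as np
import pytest
from hypothesis import settings

from conflictpci import GeneratorConfig, generate_survey

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


def small_config(**overrides) -> GeneratorConfig:
    """A scaled-down two-country sampling frame for fast tests."""
    base = dict(
        n_municipalities={"Norway": 36, "Sweden": 24},
        n_counties={"Norway": 6, "Sweden": 4},
        seed=1234,
    )
    base.update(overrides)
    return GeneratorConfig(**base)


@pytest.fixture(scope="session")
def small_survey():
    """One small generated survey + regions pair, shared across tests."""
    return generate_survey(small_config())


@pytest.fixture(scope="session")
def default_survey():
    """A full-design survey (429 + 280 municipalities) at the default config."""
    return generate_survey(GeneratorConfig(seed=20130724 % (2**31)))


@pytest.fixture
def rng():
    return np.random.default_rng(99)
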