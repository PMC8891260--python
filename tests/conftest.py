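import pytest
from hypothesis import settings

from vaxtea import build_scenarios, load_config

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")
from vaxtea.config import PLATFORMS


@pytest.fixture(scope="session")
def cfg():
    return load_config()


@pytest.fixture(scope="session")
def designs(cfg):
    """Moderate quasi-random designs per platform for distribution checks."""
    return {
        p: build_scenarios(cfg.platform(p).factor_set, 2048, scramble=True, seed=7)
        for p in PLATFORMS
    }


@pytest.fixture(scope="session")
def full_designs(cfg):
    """Study-sized 10,000-scenario designs per platform."""
    return {
        p: build_scenarios(cfg.platform(p).factor_set, 10_000, scramble=True, seed=1)
        for p in PLATFORMS
    }
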