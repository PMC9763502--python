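import numpy as np
import pytest

from xylosim.params import ModelParams, ScenarioConfig


@pytest.fixture(scope="session")
def params() -> ModelParams:
    return ModelParams()


@pytest.fixture(scope="session")
def default_scenario() -> ScenarioConfig:
    return ScenarioConfig()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def short_climate():
    """Five years of synthetic boreal forcing shared across engine tests."""
    from xylosim.climate import synthesize_climate

    return synthesize_climate(64.35, range(1991, 1996), seed=777)
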