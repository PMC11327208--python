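import numpy as np
import pytest

from planlens.env import EnvConfig, default_config


@pytest.fixture(scope="session")
def config() -> EnvConfig:
    return default_config()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def make_rng(seed: int) -> np.random.Generator:
    return np.random.default_rng(seed)
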