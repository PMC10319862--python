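import numpy as np
import pytest

from ozfad.chem import builtin_agents
from ozfad.config import PipelineConfig


@pytest.fixture(scope="session")
def ampp():
    return builtin_agents()["AMPP"]


@pytest.fixture(scope="session")
def agents():
    return builtin_agents()


@pytest.fixture()
def config():
    return PipelineConfig()


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
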