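import warnings

import numpy as np
import pytest

from kuramet import ModelConfig, WeightKernel


@pytest.fixture(autouse=True)
def _silence_short_window_warnings():
    """Small test runs legitimately use short analysis windows."""
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=".*fewer than 10 oscillation periods.*")
        yield


@pytest.fixture
def tiny_config() -> ModelConfig:
    """A 3+2 oscillator configuration with every coupling active."""
    return ModelConfig(N=3, M=2, F_GO=0.1, F_MO=0.08, seed=42)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
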