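import numpy as np
import pytest

from refugesim import ModelParams


@pytest.fixture
def small_params() -> ModelParams:
    """Default rates on a small lattice for fast runs."""
    return ModelParams(rows=20, cols=20, steps=5, IF=50)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
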