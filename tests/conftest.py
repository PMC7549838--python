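import numpy as np
import pytest

from lilymorph import FlowerParams


@pytest.fixture
def defaults() -> FlowerParams:
    """The reference parameter set (100 organs, 20 tepals, half-open)."""
    return FlowerParams()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260926)
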