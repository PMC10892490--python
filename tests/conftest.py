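import numpy as np
import pytest

from mosshealth.bands import BandStack, BAND_ORDER
from mosshealth import synthetic


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def random_stack(rng):
    """A 24x24 stack of uniform random reflectance (thermal included)."""
    arr = rng.uniform(0.01, 0.99, size=(6, 24, 24))
    return BandStack.from_array(arr)


@pytest.fixture
def easy_scene():
    return synthetic.generate(
        synthetic.default_spec("easy", height=128, width=128, seed=42)
    )


@pytest.fixture
def moderate_scene():
    return synthetic.generate(
        synthetic.default_spec("moderate", height=128, width=128, seed=43)
    )


def constant_stack(value: float = 0.4, h: int = 8, w: int = 8) -> BandStack:
    return BandStack.from_array(np.full((6, h, w), value))


def pixel_stack(**reflectance) -> BandStack:
    """1x1 stack with the given band reflectances (others 0.5)."""
    vals = {n: 0.5 for n in BAND_ORDER}
    vals.update(reflectance)
    return BandStack.from_array(np.array([[[vals[n]]] for n in BAND_ORDER]))
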