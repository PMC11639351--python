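import numpy as np
import pytest

from tctnet.config import ModelConfig
from tctnet.model import TCTNet
from tctnet.phantoms import PhantomSpec, generate_phantom


@pytest.fixture(scope="session")
def tiny_model() -> TCTNet:
    """Desk-scale model (widths 8/16/32/64) shared across read-only tests."""
    return TCTNet(ModelConfig.tiny(seed=0))


@pytest.fixture(scope="session")
def small_phantom():
    """A 32^3 phantom with a single nested lesion."""
    spec = PhantomSpec(shape=(32, 32, 32), lesion_radius_range=(5.0, 7.0), seed=7)
    return generate_phantom(spec)


@pytest.fixture(scope="session")
def default_phantom():
    """A default-spec phantom (128^3, one r~10 lesion, ~0.2% lesion fraction)."""
    return generate_phantom(PhantomSpec(seed=3))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
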