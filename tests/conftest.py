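import numpy as np
import pytest

from uterseg.core import BinaryMask, IntensityVolume, PipelineConfig
from uterseg.phantom import ColonTube, Ellipsoid, PhantomSpec


@pytest.fixture
def rng():
    return np.random.default_rng(20260925)


@pytest.fixture
def config():
    return PipelineConfig()


@pytest.fixture
def fast_config():
    """Pipeline config with registration off (tests that do not exercise it)."""
    return PipelineConfig(registration_enabled=False)


@pytest.fixture
def small_spec():
    """Half-scale phantom for seconds-scale registration tests."""
    return PhantomSpec(
        shape=(48, 48, 12),
        spacing=(1.0, 1.0, 3.0),
        uterus=Ellipsoid((24.0, 24.0, 6.0), (12.0, 9.0, 4.0)),
        colon=ColonTube((12.5, 6.0), 3.0, (12, 36)),
        fibroid_holes=(Ellipsoid((20.0, 22.0, 6.0), (3.0, 2.5, 1.5)),),
    )


def random_mask(rng, shape=(16, 16, 4), p=0.3, spacing=(1.0, 1.0, 1.0)):
    return BinaryMask(rng.random(shape) < p, spacing)


def blob_mask(shape, center, radius, spacing=(1.0, 1.0, 1.0)):
    idx = np.indices(shape, dtype=float)
    d2 = sum((idx[d] - center[d]) ** 2 for d in range(3))
    return BinaryMask(d2 <= radius**2, spacing)
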