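import numpy as np
import pytest

import clauseg as cs


@pytest.fixture(scope="session")
def bundle():
    """Default right-hemisphere phantom (96^3, 0.7 mm isotropic, seed 1)."""
    return cs.generate_phantom(cs.PhantomSpec(seed=1))


@pytest.fixture(scope="session")
def segmented(bundle):
    """Full-pipeline segmentation of the default phantom with default params."""
    return cs.segment_claustrum(bundle.t1w, bundle.putamen, bundle.csf, cs.RIGHT)


@pytest.fixture(scope="session")
def small_bundle():
    """Smaller phantom for I/O and CLI tests."""
    return cs.generate_phantom(cs.PhantomSpec(shape=(64, 64, 64), seed=3))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_mask(rng, shape=(12, 10, 9), density=0.2, spacing=(1.0, 1.0, 1.0)):
    return cs.BinaryMask(rng.random(shape) < density, spacing)
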