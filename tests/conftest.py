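import numpy as np
import pytest

from craniofill.phantom import PhantomSpec, generate_phantom
from craniofill.volume import BinaryVolume


@pytest.fixture(scope="session")
def default_phantom() -> BinaryVolume:
    """One cranial-vault shell at the generator's default resolution."""
    return generate_phantom(PhantomSpec(seed=7))


@pytest.fixture(scope="session")
def coarse_phantom() -> BinaryVolume:
    """Desk-scale shell used for defect and training tests."""
    return generate_phantom(
        PhantomSpec(dims=(32, 32, 24), spacing=(6.0, 6.0, 6.4), seed=3)
    )


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def random_binary_volume(rng, shape=(8, 8, 8), p=0.3, spacing=(1.0, 1.0, 1.0)):
    return BinaryVolume(
        (rng.random(shape) < p).astype(np.uint8), spacing=spacing
    )
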