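import numpy as np
import pytest

from tumorseg.phantoms import PhantomSpec, generate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def phantom_batch():
    """100 default-condition phantoms shared by read-only tests."""
    spec = PhantomSpec(seed=11)
    return spec, generate_dataset(spec, 100)


@pytest.fixture(scope="session")
def smoke_phantoms():
    """Small 32x32 all-tumor phantoms for training smoke tests."""
    spec = PhantomSpec(image_height=32, image_width=32, tumor_probability=1.0,
                       tumor_semi_axes_range=(4.0, 9.0), tumor_contrast=0.4,
                       noise_sigma=0.03, seed=7)
    return spec, generate_dataset(spec, 20)
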