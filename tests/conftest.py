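import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20231109)


@pytest.fixture
def two_gaussian_image(rng):
    """Bimodal grayscale image (modes 60 and 180, sd 10)."""
    lo = rng.normal(60, 10, size=(64, 64))
    hi = rng.normal(180, 10, size=(64, 64))
    img = np.concatenate([lo, hi], axis=0)
    return np.clip(np.rint(img), 0, 255).astype(np.uint8)


@pytest.fixture
def spliced_sample():
    from crackfrac.synthetic import gen_spliced

    return gen_spliced(n=2000, seed=7)
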