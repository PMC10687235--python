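import hypothesis
import numpy as np
import pytest

from ihdrisk.synth import PhantomSpec, make_phantom

hypothesis.settings.register_profile(
    "default", derandomize=True, deadline=None, max_examples=50
)
hypothesis.settings.load_profile("default")


@pytest.fixture(scope="session")
def default_spec() -> PhantomSpec:
    return PhantomSpec()


@pytest.fixture(scope="session")
def small_spec() -> PhantomSpec:
    # smaller grid keeps image-heavy tests fast without changing geometry
    return PhantomSpec(image_size=128, pixel_spacing_mm=(3.0, 3.0), seed=7)


@pytest.fixture(scope="session")
def phantom(default_spec):
    return make_phantom(default_spec)


@pytest.fixture(scope="session")
def small_phantom(small_spec):
    return make_phantom(small_spec)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
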