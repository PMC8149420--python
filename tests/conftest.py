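import numpy as np
import pytest

from histoct import PhantomSpec, RasterImage, generate_pair


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def rgb_image(rng):
    return RasterImage(rng.integers(0, 256, (40, 60, 3)).astype(float), bit_depth=8)


@pytest.fixture
def grey_image(rng):
    return RasterImage(rng.integers(0, 256, (48, 48)).astype(float), bit_depth=8)


@pytest.fixture
def aligned_phantom():
    """A noise-free, perfectly aligned CT/histology phantom pair."""
    spec = PhantomSpec(seed=11, size=(160, 160), elastic_max_px=0.0, noise_sigma=0.0)
    return generate_pair(spec)


@pytest.fixture
def deformed_phantom():
    """A phantom pair with known rigid + elastic ground truth."""
    spec = PhantomSpec(
        seed=21,
        size=(200, 200),
        rigid_rotation_deg=12.0,
        rigid_translation_px=(8.0, -5.0),
        elastic_max_px=6.0,
        elastic_spacing_px=64.0,
        noise_sigma=1.0,
    )
    return generate_pair(spec)
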