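import numpy as np
import pytest

from modclahe import GrayImage, OpacitySpec, PhantomSpec, generate_phantom


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def low_contrast_spec(seed: int, size: int = 128) -> PhantomSpec:
    """The low-contrast noisy study condition used for quality-effect checks."""
    return PhantomSpec(
        size=(size, size),
        lung_contrast=25.0,
        rib_amplitude=6.0,
        opacity=OpacitySpec(center=(0.52 * size, 0.30 * size), radius=9.0, amplitude=18.0),
        noise_sigma=6.0,
        seed=seed,
    )


@pytest.fixture
def noisy_phantom():
    """One moderately noisy 64x64 phantom image."""
    img, _, _ = generate_phantom(low_contrast_spec(seed=3, size=64))
    return img


def random_image(rng, shape=(64, 64), levels=256) -> GrayImage:
    return GrayImage(rng.integers(0, levels, size=shape), levels=levels)
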