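import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from vebird.geometry import Ellipse
from vebird.synthetic import (
    EyeImageSpec,
    TissueColorModel,
    generate_eye_image,
    generate_tissue_patches,
)


@pytest.fixture(scope="session")
def noisy_ellipse_sample():
    """One noisy edge image with an elliptical iris and known ground truth."""
    spec = EyeImageSpec(
        iris_ellipse=Ellipse(128.0, 128.0, 60.0, 40.0, 0.3),
        n_contour_points=200,
        noise_fraction=0.3,
        seed=5,
    )
    return generate_eye_image(spec)


@pytest.fixture(scope="session")
def noisy_circle_sample():
    spec = EyeImageSpec(
        iris_ellipse=Ellipse(128.0, 128.0, 55.0, 55.0, 0.0),
        n_contour_points=200,
        noise_fraction=0.3,
        seed=7,
    )
    return generate_eye_image(spec)


@pytest.fixture(scope="session")
def clean_patch_set():
    """Noise-free tissue patches, 5 per grade."""
    return generate_tissue_patches(TissueColorModel(noise_scale=0.0, seed=3), 5)


@pytest.fixture(scope="session")
def noisy_patch_set():
    """sigma=10 tissue patches, 40 per grade."""
    return generate_tissue_patches(TissueColorModel(noise_scale=10.0, seed=11), 40)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
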