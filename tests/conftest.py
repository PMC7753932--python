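"""Shared fixtures: phantoms at full (0.8 mm) and desk (1.6 mm) scale."""

import numpy as np
import pytest

from hip3d.phantom import PhantomSpec, generate_phantom

#: desk-scale acquisition used by the training/cross-validation tests
DESK = dict(voxel_size_mm=1.6, volume_shape=(64, 64, 64))


@pytest.fixture(scope="session")
def default_sample():
    """Noise-free default phantom (hemispherical cup, 0.8 mm voxels)."""
    return generate_phantom(PhantomSpec())


@pytest.fixture(scope="session")
def dysplastic_sample():
    """Noise-free dysplastic phantom (60 degree cup)."""
    return generate_phantom(PhantomSpec(cup_half_angle_deg=60.0))


@pytest.fixture(scope="session")
def desk_sample():
    """Noise-free phantom at desk scale (1.6 mm, 64^3)."""
    return generate_phantom(PhantomSpec(**DESK))


@pytest.fixture(scope="session")
def noisy_desk_samples():
    """Small desk-scale training cohort with noise and bias."""
    from hip3d.phantom import make_dataset

    base = PhantomSpec(noise_sd=5.0, bias_field_amplitude=0.05, **DESK)
    return make_dataset(6, seed=29, base=base)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
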