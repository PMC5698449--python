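import numpy as np
import pytest

from seednir import SceneSpec, calibrate, generate_scene, segment_seeds, select_segmentation_band


@pytest.fixture(scope="session")
def clean_spec():
    """Zero-noise, zero-scatter, unit-offset scene: 3 seeds per class."""
    return SceneSpec(
        n_seeds_per_class=(3, 3), noise_sd=0.0, scatter_sd=0.0, class_offset=1.0, rng_seed=11
    )


@pytest.fixture(scope="session")
def clean_scene(clean_spec):
    return generate_scene(clean_spec)


@pytest.fixture(scope="session")
def clean_reflectance(clean_scene):
    raw, dark, white, truth = clean_scene
    return calibrate(raw, dark, white), truth


@pytest.fixture(scope="session")
def clean_seeds(clean_reflectance):
    rho, _ = clean_reflectance
    return segment_seeds(select_segmentation_band(rho))


@pytest.fixture(scope="session")
def default_wavelengths():
    return SceneSpec().wavelengths


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
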