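import numpy as np
import pytest

from xcelunet.synthetic import PhantomParams, generate_phantom


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def small_phantom():
    """A 48^3 phantom with a 5 mm osteophyte, narrowed-to-absent joint space
    and eccentric head (truth: os=1, js=2, hsa=1)."""
    return generate_phantom(PhantomParams(
        grid_shape=(48, 48, 48), spacing_mm=1.0, head_radius_mm=10.0,
        osteophyte_height_mm=5.0, osteophyte_count=2, joint_gap_mm=0.5,
        eccentric_shift_mm=4.0, noise_sd_hu=15.0, seed=3,
    ))


@pytest.fixture(scope="session")
def clean_phantom():
    """A noiseless concentric phantom with physiological joint space."""
    return generate_phantom(PhantomParams(
        grid_shape=(48, 48, 48), spacing_mm=1.0, head_radius_mm=10.0,
        joint_gap_mm=4.0, noise_sd_hu=0.0, seed=1,
    ))
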