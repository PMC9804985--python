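import numpy as np
import pytest

from isletquant.experiments import SIM_SEG_CONFIG, sim_params
from isletquant.synthetic import render_if_image, sample_islet_geometry


@pytest.fixture
def sim_cfg():
    """Segmentation config matched to the small simulation frame."""
    return SIM_SEG_CONFIG


@pytest.fixture
def noise_free_params():
    return sim_params(islet_area_fraction_target=0.008, noise_model=(0.0, 0.0))


@pytest.fixture
def noisy_params():
    return sim_params(islet_area_fraction_target=0.008)


def make_field(params, seed=1):
    rng = np.random.default_rng(seed)
    gt = sample_islet_geometry(params, rng)
    img = render_if_image(gt, params, rng)
    return gt, img


@pytest.fixture
def noise_free_field(noise_free_params):
    return make_field(noise_free_params)


@pytest.fixture
def noisy_field(noisy_params):
    return make_field(noisy_params)
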