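import numpy as np
import pytest

from wcemlda import SyntheticConfig, build_bank, generate_dataset, generate_image
from wcemlda.experiments import make_bank_fixtures


@pytest.fixture(scope="session")
def default_config():
    return SyntheticConfig()


@pytest.fixture(scope="session")
def clean_config():
    """No illumination variability: pixels follow the class color models exactly."""
    return SyntheticConfig(illumination_sd=0.0, gradient_sd=0.0)


@pytest.fixture(scope="session")
def small_config():
    """Small rasters for fast unit tests."""
    return SyntheticConfig(image_size=(96, 96))


@pytest.fixture(scope="session")
def bleeding_image(default_config):
    return generate_image("B", default_config, seed=7)


@pytest.fixture(scope="session")
def small_bank(small_config):
    """Bank of 2 pixel-labeled fixtures per disease on small rasters."""
    return build_bank(make_bank_fixtures(2, small_config, seed=0))


@pytest.fixture(scope="session")
def tiny_dataset(small_config):
    """12 evaluation images, 3 per class, on small rasters."""
    images, manifest = generate_dataset(
        {"B": 3, "U": 3, "T": 3, "N": 3}, small_config, seed=5
    )
    return images, manifest


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
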