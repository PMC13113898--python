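import numpy as np
import pytest

from edgebcs import generate_synthetic_dataset


@pytest.fixture(scope="session")
def tiny_dataset(tmp_path_factory):
    """Small deterministic synthetic detection set shared across tests."""
    root = tmp_path_factory.mktemp("synth")
    manifest = generate_synthetic_dataset(
        root, n_animals=6, images_per_session=1, blur_fraction=1 / 3,
        seed=7, image_size=(160, 160))
    return root, manifest


@pytest.fixture()
def rng():
    return np.random.default_rng(123)
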