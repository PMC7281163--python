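import numpy as np
import pytest

import sonodeform as sd


@pytest.fixture(scope="session")
def small_config():
    """A fast cohort: 4+4 cells, 48x48 px at 1 µm/px."""
    return sd.SyntheticConfig(
        n_cells_per_class=4,
        image_size=(48, 48),
        pixel_pitch=1.0,
        radius_range=(5.0, 9.0),
        seed=11,
    )


@pytest.fixture(scope="session")
def small_records(small_config):
    return sd.generate_dataset(small_config)


@pytest.fixture(scope="session")
def small_combined(small_records):
    return sd.combine_dataset(small_records)


@pytest.fixture(scope="session")
def small_augmented(small_combined):
    images, manifest = small_combined
    return sd.augment_dataset(
        images, manifest, sd.AugmentConfig(n_augment_per_cell=5, seed=2)
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
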