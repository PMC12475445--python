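import numpy as np
import pytest

from microniche.synthetic import SyntheticConfig, generate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def small_config():
    return SyntheticConfig(
        seed=7,
        n_tumors=2,
        rois_per_compartment=1,
        tumor_cells_per_roi=(60, 90),
        niche_cells_per_roi=150,
        roi_size_um=300.0,
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return generate_cohort(small_config)
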