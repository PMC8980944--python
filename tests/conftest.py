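import numpy as np
import pytest

from strokeseg.synthetic import SyntheticConfig, generate_cohort


@pytest.fixture(scope="session")
def tiny_cohort():
    """Four small subjects (8 x 64 x 64) for fast integration tests."""
    cfg = SyntheticConfig(n_slices=8, slice_height=64, slice_width=64,
                          lesion_count_range=(1, 1),
                          lesion_radius_range=(4.0, 7.0), seed=11)
    return cfg, generate_cohort(4, cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
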