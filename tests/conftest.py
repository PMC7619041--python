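import numpy as np
import pytest

from prmix.data_model import LabeledSample, RegionTaxonomy
from prmix.phantom import PhantomConfig, generate_dataset


@pytest.fixture
def toy_taxonomy() -> RegionTaxonomy:
    """Two primary regions: subregions {1, 2} -> 1, {3} -> 2."""
    return RegionTaxonomy(
        subregion_to_primary={1: 1, 2: 1, 3: 2},
        primary_names={1: "A", 2: "B"},
    )


def make_sample(labels, n_channels=2, sample_id="s", rng=None):
    """Sample with the given label map and reproducible random intensities."""
    labels = np.asarray(labels, dtype=np.int64)
    rng = rng or np.random.default_rng(abs(hash(sample_id)) % 2**31)
    image = rng.uniform(0.0, 1.0, size=labels.shape + (n_channels,))
    return LabeledSample(image, labels, sample_id)


@pytest.fixture
def small_phantom_config() -> PhantomConfig:
    """Down-scaled phantom grid for fast unit tests."""
    return PhantomConfig(
        grid=(64, 96), n_primary=5, subregions_per_primary=(2, 4), dropout_prob=0.1
    )


@pytest.fixture
def phantom_dataset(small_phantom_config):
    """Six small phantoms sharing one taxonomy."""
    return generate_dataset(6, small_phantom_config, seed=11)
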