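import numpy as np
import pytest
from hypothesis import settings

import ligandblob as lb

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def shape_dataset_small():
    """5-class shape dataset, 20 clouds/class — shared across model tests."""
    return lb.make_shape_dataset(n_classes=5, n_per_class=20, seed=7)


@pytest.fixture
def random_grid(rng):
    """A sparse random nonnegative grid with a few connected structures."""
    values = np.zeros((12, 10, 8))
    mask = rng.random(values.shape) < 0.15
    values[mask] = rng.random(mask.sum()) + 0.5
    return lb.VoxelGrid(values=values, spacing=0.2)
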