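import numpy as np
import pytest

from striocon import phantom, pipeline
from striocon.core import BaitGrouping, VolumeGrid


@pytest.fixture(scope="session")
def default_truth():
    return phantom.make_phantom(rng_seed=7)


@pytest.fixture(scope="session")
def baits():
    return BaitGrouping()


@pytest.fixture(scope="session")
def parcellation(default_truth, baits):
    """Round-1 outputs on the default phantom: (conn, p_strio, p_matrix, masks)."""
    return pipeline.parcellation_round(default_truth, baits=baits, rng_seed=70)


@pytest.fixture
def small_grid():
    affine = np.diag([2.0, 2.0, 2.0, 1.0])
    return VolumeGrid(shape=(6, 6, 6), affine=affine)
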