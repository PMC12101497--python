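import numpy as np
import pytest

from wmcpm.connectome import EdgeIndexMap
from wmcpm.synthetic_data import AtlasPartition, make_atlas


@pytest.fixture(scope="session")
def toy_atlas() -> AtlasPartition:
    """10 nodes in 3 networks (contiguous blocks for hand enumeration)."""
    return make_atlas(10, [3, 4, 3], ["A", "B", "C"], seed=None)


@pytest.fixture(scope="session")
def toy_emap() -> EdgeIndexMap:
    return EdgeIndexMap(10)


@pytest.fixture(scope="session")
def small_cohort():
    """A 30-subject, 20-node cohort with a planted 5-edge signal."""
    from wmcpm.synthetic_data import simulate_dataset

    return simulate_dataset(
        n_subjects=30,
        n_nodes=20,
        network_sizes=[8, 6, 6],
        network_names=["alpha", "beta", "gamma"],
        n_timepoints=120,
        n_signal_edges=5,
        target_network="beta",
        snr=2.0,
        seed=11,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(42)
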