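import numpy as np
import pytest

from groupnet import CohortSpec, GroupBlockSpec, NetworkSpec, generate_cohort, split_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A small learnable cohort shared across tests (default structure)."""
    return generate_cohort(CohortSpec(n=1200, seed=7))


@pytest.fixture(scope="session")
def small_split(small_cohort):
    return split_cohort(small_cohort, 0.7, seed=0)


@pytest.fixture
def tiny_net_spec():
    """A reduced architecture that trains in well under a second."""
    block = GroupBlockSpec(
        partitions=(2, 2), kernels_per_layer=(8, 8), cluster_layers=1,
        cluster_channels=8, kernel_size=3,
    )
    def make(variant="BR", **kwargs):
        kwargs.setdefault("fc_units", 16)
        return NetworkSpec(variant=variant, block=block, **kwargs)
    return make


@pytest.fixture
def rng():
    return np.random.default_rng(123)
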