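import numpy as np
import pytest

from neurofuse import CohortSpec, gen_cohort
from neurofuse.core_io import make_atlas_spec


@pytest.fixture(scope="session")
def small_atlas():
    """Two homolog pairs plus an average-signal node (5 graph nodes)."""
    return make_atlas_spec("toy", n_pairs=2)


@pytest.fixture(scope="session")
def ho_atlas():
    """Bilateral cortical atlas: 55 homolog pairs + average node."""
    return make_atlas_spec("ho", n_pairs=55)


@pytest.fixture(scope="session")
def smoke_cohort():
    """Tiny planted-signal cohort reused by the cheaper integration tests."""
    return gen_cohort(CohortSpec(n_subjects=20, volume_shape=(12, 12, 12),
                                 blob_radius=2, pairs_per_atlas=5,
                                 n_timepoints=30, n_frames=4, seed=7))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
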