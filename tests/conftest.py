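import numpy as np
import pytest

import disconnectome as dc


@pytest.fixture(scope="session")
def identity_grid():
    return dc.VolumeGrid((64, 64, 64), np.eye(4))


@pytest.fixture(scope="session")
def phantom():
    return dc.make_phantom(seed=1)


@pytest.fixture(scope="session")
def tractogram(phantom):
    """Small tractogram shared by mapping tests (~300 fibers)."""
    return dc.make_tractogram(phantom, n_fibers_per_pair=20, seed=1)


@pytest.fixture(scope="session")
def voxel_index(tractogram):
    return dc.build_voxel_index(tractogram)


@pytest.fixture(scope="session")
def small_cohort_dir(tmp_path_factory):
    """Tiny two-timepoint dataset written to disk (10 controls / 10
    patients, 180-fiber tractogram)."""
    ph = dc.make_phantom(seed=2)
    tg = dc.make_tractogram(ph, n_fibers_per_pair=30, seed=2)
    co = dc.simulate_cohort(ph, tg, 10, 10, longitudinal=True, seed=8)
    out = tmp_path_factory.mktemp("dataset")
    dc.write_cohort(co, out)
    return out
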