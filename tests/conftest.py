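import numpy as np
import pytest

from dgmqsm.grids import GridSpec
from dgmqsm.synthetic import (
    AcquisitionParams,
    make_dgm_phantom,
    synthesize_multiecho,
)

# 32^3 grid at 1.5 mm spans the same 48 mm field of view as the default
# 64^3 grid, so the default structure geometry fits; unit tests use it to
# keep the inversions fast.
COARSE_GRID = GridSpec(shape=(32, 32, 32), voxel_size=(1.5, 1.5, 1.5))


@pytest.fixture(scope="session")
def coarse_phantom():
    return make_dgm_phantom(grid=COARSE_GRID, seed=0, n_lesions=6)


@pytest.fixture(scope="session")
def coarse_signal(coarse_phantom):
    return synthesize_multiecho(coarse_phantom, AcquisitionParams(), seed=0)


@pytest.fixture(scope="session")
def default_phantom():
    return make_dgm_phantom(seed=0)
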