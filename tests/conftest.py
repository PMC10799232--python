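import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from cycleproc.synthetic_acquisition import generate_phantom, write_acquisition
from cycleproc.testing import small_descriptor


@pytest.fixture(scope="session")
def descriptor():
    """2x2 grid, 2 channels, 4 cycles, single Z plane, 96 px tiles."""
    return small_descriptor(n_z=1, overlap_fraction=0.2)


@pytest.fixture(scope="session")
def phantom(descriptor):
    return generate_phantom(
        descriptor, n_nuclei=20, seed=11, af_texture=200.0, max_drift=3
    )


@pytest.fixture(scope="session")
def acquisition_dir(tmp_path_factory, phantom):
    out = tmp_path_factory.mktemp("acq") / "raw"
    write_acquisition(phantom, out)
    return out


@pytest.fixture
def rng():
    return np.random.default_rng(7)
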