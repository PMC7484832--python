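import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from cps.machine import MachineState, default_geometry


@pytest.fixture(scope="session")
def geom():
    return default_geometry()


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)


@pytest.fixture
def lateral_gantry_state():
    """Gantry at 90 deg with the couch in a typical treatment position."""
    return MachineState(
        gantry_angle=90.0,
        couch_lng_readout=95.0,
        couch_vrt_readout=16.6,
        couch_rtn=0.0,
    )
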