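import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from shapims import phantom
from shapims.ims_data import IMSDataset
from shapims.model import MarkerDiscovery


@pytest.fixture
def tiny_ds():
    """2x2 full grid, 3 features, known values."""
    X = np.array([
        [1.0, 5.0, 1.0],
        [2.0, 6.0, 1.0],
        [3.0, 7.0, 1.0],
        [4.0, 8.0, 1.0],
    ])
    coords = np.array([[0, 0], [0, 1], [1, 0], [1, 1]])
    mz = np.array([100.0, 200.0, 300.0])
    return IMSDataset(X, coords, mz, name="tiny")


@pytest.fixture(scope="session")
def demo_phantom():
    """The canonical two-region demo phantom at seed 1."""
    ds, masks, gt = phantom.generate_phantom(phantom.demo_config(1))
    return ds, masks, gt


@pytest.fixture(scope="session")
def demo_results():
    """A full discovery fit on the demo phantom (100 trees, depth 4)."""
    model = MarkerDiscovery.from_phantom(phantom.demo_config(1), "target")
    return model.fit(seed=1)
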