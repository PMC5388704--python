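import numpy as np
import pytest

import ke4dflow as k


@pytest.fixture(scope="session")
def uniform_phantom():
    """1000 ROI voxels of 2 mm, plug flow 100 cm/s: closed-form KE 4.2 mJ."""
    return k.make_uniform_phantom(100.0, grid=(20, 20, 20),
                                  spacing=(2.0, 2.0, 2.0), n_phases=8,
                                  roi_shape=(10, 10, 10))


@pytest.fixture(scope="session")
def ventricle_phantoms():
    """One clean ventricle phantom per cycle pattern, 20 phases, 32³ grid."""
    return {
        pattern: k.make_ventricle_phantom(pattern, n_phases=20, seed=7)
        for pattern in ("systolic_dominant", "diastolic_dominant", "plateau")
    }


@pytest.fixture
def eddy_plane():
    """First-order plane: offsets cm/s, gradients cm/s per mm."""
    return np.array([
        [3.0, 0.1, -0.05, 0.0],
        [1.0, 0.0, 0.02, 0.0],
        [-2.0, 0.01, 0.0, 0.03],
    ])
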