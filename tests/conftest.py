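import numpy as np
import pandas as pd
import pytest

from dmil.preprocess import CTVolume


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def ramp_volume():
    """10x10x10 grid at 2 mm spacing with a linear HU ramp along x."""
    x = np.arange(10, dtype=float)
    voxels = np.broadcast_to(x[:, None, None] * 10.0 - 500.0, (10, 10, 10)).copy()
    return CTVolume(voxels, (2.0, 2.0, 2.0), id="ramp")


@pytest.fixture
def iso_volume(rng):
    """128^3 random HU volume already at 1 mm isotropic spacing."""
    voxels = rng.normal(-500.0, 100.0, (128, 128, 128))
    return CTVolume(voxels, (1.0, 1.0, 1.0), id="iso")


@pytest.fixture
def cohort_manifest():
    """301-bag manifest with the study's 163/138 class sizes."""
    n1, n0 = 163, 138
    return pd.DataFrame(
        {
            "bag_id": [f"b{i:03d}" for i in range(n1 + n0)],
            "label": [1] * n1 + [0] * n0,
        }
    )
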