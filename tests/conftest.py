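import numpy as np
import pytest

from spikemap import ArrayGeometry, Recording


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_geometry():
    return ArrayGeometry(n_rows=2, n_cols=2, pitch_um=42.0)


@pytest.fixture
def noise_recording(rng, small_geometry):
    """4-channel, 1 s of Gaussian noise (sd 10 uV) at 18 kHz."""
    v = rng.normal(0.0, 10.0, size=(4, 18000)).astype(np.float32)
    return Recording(v, 18000.0, small_geometry)
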