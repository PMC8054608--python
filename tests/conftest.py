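import numpy as np
import pytest

from pasvd.beamform import beamform_cine
from pasvd.phantom import PhantomConfig, _clutter_heavy_config, simulate_channel_cine


@pytest.fixture(scope="session")
def clutter_heavy():
    """Fixed-seed clutter-heavy phantom (channel cine + ground truth)."""
    return simulate_channel_cine(_clutter_heavy_config(seed=7))


@pytest.fixture(scope="session")
def clutter_heavy_das(clutter_heavy):
    """DAS-beamformed clutter-heavy cine, shared across tests."""
    cine, _ = clutter_heavy
    return beamform_cine(cine)


@pytest.fixture(scope="session")
def clean_wall():
    """Noise- and clutter-free moving-wall phantom (small, fast)."""
    return simulate_channel_cine(PhantomConfig(seed=11, n_frames=48))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
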