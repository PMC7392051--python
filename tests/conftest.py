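import numpy as np
import pytest

from disorder import synth


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def ds_motion():
    """64x64, 8 coils, 8 segments, rotations and translations, 30 dB."""
    cfg = synth.SimulationConfig(n=64, n_coils=8, n_segments=8,
                                 theta_deg=8.0, trans_mm=2.0, snr_db=30.0,
                                 seed=2)
    return synth.simulate(cfg)


@pytest.fixture(scope="session")
def ds_clean():
    """64x64, zero motion, noiseless."""
    cfg = synth.SimulationConfig(n=64, n_coils=8, n_segments=16,
                                 theta_deg=0.0, snr_db=np.inf, seed=4)
    return synth.simulate(cfg)


@pytest.fixture(scope="session")
def phantom64():
    return synth.make_phantom(64)


@pytest.fixture(scope="session")
def maps64():
    return synth.make_coilmaps(64, 8)
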