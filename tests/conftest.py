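import dataclasses

import numpy as np
import pytest

from nptpipe.frp import ElectrodeMontage, EpochConfig
from nptpipe.geometry import ScreenGeometry
from nptpipe.simulate import EEGParams, GroupProfile, SimConfig, simulate_session


@pytest.fixture(scope="session")
def geometry():
    return ScreenGeometry()


@pytest.fixture(scope="session")
def montage():
    return ElectrodeMontage()


@pytest.fixture(scope="session")
def epoch_config():
    return EpochConfig()


def small_sim_config(**overrides) -> SimConfig:
    """A session small enough for fast tests: 2 groups x 2 subjects, 8 images."""
    defaults = dict(
        n_images=8,
        n_face_images=3,
        groups=(("HC", 2), ("PDP", 2)),
        seed=11,
    )
    defaults.update(overrides)
    return dataclasses.replace(SimConfig(), **defaults)


@pytest.fixture(scope="session")
def small_session():
    return simulate_session(small_sim_config())


@pytest.fixture(scope="session")
def quiet_eeg_params():
    """Noise-free EEG without conditioning calibration (exactness checks)."""
    return EEGParams(noise_sd_uv=0.0, spike_amp_uv=0.0, blink_peak_uv=0.0,
                     conditioning_band_hz=None)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
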