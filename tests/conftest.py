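import numpy as np
import pytest

from iq67kit import synth_data


@pytest.fixture(scope="session")
def small_cfg() -> synth_data.SynthConfig:
    """A reduced-size study configuration for fast unit tests."""
    return synth_data.SynthConfig(
        seed=17, n_sun=6, n_decoy_iq=3, n_background=12,
        background_length_range=(150, 400),
    )


@pytest.fixture(scope="session")
def small_proteome(small_cfg):
    return synth_data.generate_proteome(small_cfg)


@pytest.fixture(scope="session")
def study_cfg() -> synth_data.SynthConfig:
    """The full default study conditions (24 family / 9 decoy / 100 background)."""
    return synth_data.SynthConfig(seed=17)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
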