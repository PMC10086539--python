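import numpy as np
import pytest

from strikelab.io import TrialMeta
from strikelab.synthetic import StrikeScenario


@pytest.fixture
def clean_walled() -> StrikeScenario:
    """Noiseless walled-setup trial: tail pinned, plate sees full head force."""
    return StrikeScenario(noise_sd_force=0.0, noise_sd_position=0.0, setup="walled")


@pytest.fixture
def clean_open() -> StrikeScenario:
    """Noiseless open-setup trial: tail recoil caps the FA/V ratio below mu."""
    return StrikeScenario(noise_sd_force=0.0, noise_sd_position=0.0, setup="open")


@pytest.fixture
def cal_meta() -> TrialMeta:
    """Metadata for direct-profile calibration trials (typical juvenile)."""
    return TrialMeta(
        individual_id="cal", setup="walled", trial_id="cal", mass=0.586, mu=0.30
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20230126)
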