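import numpy as np
import pytest

from beatssep.synthdata import SimConfig


@pytest.fixture
def rng():
    return np.random.default_rng(20250929)


@pytest.fixture
def tiny_cfg():
    """A fast EEG-domain configuration: the population model is the default
    one, only the recording dimensions are shrunk."""
    return SimConfig(
        n_labs=1,
        subjects_per_lab=2,
        trials_imagery=2,
        trials_control=2,
        n_channels=2,
        pink_scale_uv=3.0,
        white_scale_uv=1.0,
    )
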