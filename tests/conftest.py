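import numpy as np
import pytest

from skate_events.synthetic_data import TrialSpec, simulate_trial


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def clean_trial():
    """Noiseless, jitter-free G3 trial: every detector should be exact."""
    spec = TrialSpec(subtech="G3", n_cycles=12, seed=7, noise_acc_sd=0.0,
                     noise_gyro_sd=0.0, noise_marker_sd=0.0, jitter_sd_s=0.0,
                     gyro_bias=0.0)
    return simulate_trial(spec)


@pytest.fixture(scope="session")
def noisy_trial():
    """Trial at the study's stated noise levels."""
    return simulate_trial(TrialSpec(subtech="G3", n_cycles=15, seed=21))
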