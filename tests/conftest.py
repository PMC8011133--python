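import numpy as np
import pytest

from gaitstab.preprocess import preprocess_trial
from gaitstab.synthetic import GaitSimConfig, simulate_trial

#: even-harmonics-only amplitude profile: a perfectly step-symmetric,
#: step-periodic vertical/forward pattern
SYMMETRIC_AMPS_VT = (0.0, 0.25, 0.0, 0.10, 0.0, 0.04)
SYMMETRIC_AMPS_AP = (0.0, 0.10, 0.0, 0.05, 0.0, 0.02)


def make_config(**kwargs) -> GaitSimConfig:
    defaults = dict(
        stride_time_mean=1.0,
        stride_time_jitter_sd=0.0,
        noise_sd=0.0,
        asymmetry=0.0,
        duration=30.0,
        seed=0,
    )
    defaults.update(kwargs)
    return GaitSimConfig(**defaults)


@pytest.fixture(scope="session")
def clean_trial():
    """A deterministic, jitter-free, noise-free preprocessed trunk trial."""
    return preprocess_trial(simulate_trial(make_config()))


@pytest.fixture(scope="session")
def symmetric_clean_trial():
    """Perfectly periodic, step-symmetric trunk trial (even harmonics only)."""
    cfg = make_config(
        harmonic_amps_vt=SYMMETRIC_AMPS_VT, harmonic_amps_ap=SYMMETRIC_AMPS_AP
    )
    return preprocess_trial(simulate_trial(cfg))


@pytest.fixture(scope="session")
def realistic_trial_pair():
    """Head + trunk preprocessed trials with mild jitter and noise."""
    cfg = make_config(stride_time_jitter_sd=0.02, noise_sd=0.02, seed=7)
    head = preprocess_trial(simulate_trial(cfg, "head"))
    trunk = preprocess_trial(simulate_trial(cfg, "lower_trunk"))
    return head, trunk
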