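import numpy as np
import pytest

from septrial import (SEPTemplate, SimConfig, build_1020_montage,
                      generate_run)

#: artifact-free simulation settings used when a test needs a clean run
CLEAN = dict(blinks_per_min=0.0, movement_prob=0.0)


@pytest.fixture(scope="session")
def montage():
    return build_1020_montage()


@pytest.fixture(scope="session")
def template():
    return SEPTemplate()


@pytest.fixture(scope="session")
def short_run(montage):
    """A clean 40-trial 1 Hz run reused by cheap tests."""
    cfg = SimConfig(seed=42, n_trials=40, stim_freq_hz=1.0, **CLEAN)
    return generate_run(cfg, montage)


def noiseless_config(seed=0, n_trials=10, stim_freq_hz=1.0):
    """Background-free, jitter-free settings for exact identities."""
    return SimConfig(seed=seed, n_trials=n_trials, stim_freq_hz=stim_freq_hz,
                     snr=np.inf, isi_jitter_frac=0.0, **CLEAN)


def noiseless_template():
    return SEPTemplate(amplitude_cv=0.0, latency_jitter_ms=0.0)
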