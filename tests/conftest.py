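import numpy as np
import pytest

from ddadecode import ClassDynamics, WindowSpec, gen_trialset, two_class_spec

# Study conditions reused across tests: two classes with strong delayed
# feedback differing in their generating delays -- cleanly separable -- at a
# small sampling rate so everything stays fast.
DYN_A = ClassDynamics(t1=3, t2=7, b1=-0.3, b2=-0.1, b3=0.0, noise_sd=1.0)
DYN_B = ClassDynamics(t1=4, t2=9, b1=-0.3, b2=-0.1, b3=0.0, noise_sd=1.0)


@pytest.fixture(scope="session")
def wspec():
    return WindowSpec(mode="sliding", win_len_ms=700.0, overlap=0.5)


@pytest.fixture(scope="session")
def tiny_trialset():
    """1 subject, 2 separable classes, 8 trials/class, 3 channels, fs=64."""
    spec = two_class_spec(DYN_A, DYN_B, n_subjects=1, n_trials_per_class=8,
                          fs=64.0, trial_len=2.0, n_channels=3, seed=11)
    return gen_trialset(spec)


@pytest.fixture(scope="session")
def small_sd_trialset():
    """1 subject, 2 separable classes, 10 trials/class, fs=256 -- for pipeline tests."""
    spec = two_class_spec(DYN_A, DYN_B, n_subjects=1, n_trials_per_class=10,
                          fs=256.0, trial_len=2.0, n_channels=3, seed=5)
    return gen_trialset(spec)
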