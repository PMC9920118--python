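import numpy as np
import pytest

from respiraflow import net, respsig, siggen

TINY_WS = 0.125   # width scale for CPU-sized models


@pytest.fixture(scope="session")
def clean_recording():
    """Noise-free 32-s recording at 15 BrPM with all modulations active."""
    p = siggen.SimParams(resp_freq_hz=0.25, rsa_depth=0.1, rpa_depth=0.2,
                         adr_gain=0.05, ecg_noise_sd=0.0, motion_noise_sd=0.0,
                         seed=11)
    return siggen.simulate_recording(p)


@pytest.fixture(scope="session")
def default_recording():
    """Recording with the default (mild) noise levels."""
    return siggen.simulate_recording(siggen.SimParams(seed=3))


@pytest.fixture(scope="session")
def small_windows():
    """Two dozen derived windows spanning a range of rates."""
    ds = siggen.simulate_dataset(24, seed=21)
    wins = []
    for rec in ds.recordings:
        wins.extend(respsig.make_windows(rec))
    return wins


@pytest.fixture(scope="session")
def tiny_teacher():
    return net.build_teacher(net.teacher_config(width_scale=TINY_WS, seed=1))


@pytest.fixture(scope="session")
def tiny_student():
    return net.build_student(net.student_config(width_scale=TINY_WS, seed=2))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
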