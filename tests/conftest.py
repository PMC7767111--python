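import numpy as np
import pytest

from vcgmi.synthetic_ecg import SimConfig, generate_record


@pytest.fixture(scope="session")
def noiseless_60bpm():
    """10 s noiseless record at 60 bpm (RR exactly 1 s, fs 500 Hz)."""
    return generate_record(SimConfig(duration=10.0, mean_rr=1.0, seed=1))


@pytest.fixture(scope="session")
def jittered_record():
    """20 s record with mild jitter and noise, for detection/segmentation."""
    return generate_record(
        SimConfig(duration=20.0, mean_rr=0.8, rr_jitter=0.05, noise_sd=0.02, seed=2)
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
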