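import numpy as np
import pytest

from hippoephys.synthetic_data import LfpConfig, gen_lfp
from hippoephys.types import ContinuousSignal

FS = 1250.0


@pytest.fixture(scope="session")
def default_lfp():
    """One 100-s synthetic LFP with ground truth, shared across tests."""
    return gen_lfp(LfpConfig(duration_s=100.0, seed=42))


@pytest.fixture
def sine_factory():
    def make(freq, duration_s=10.0, fs=FS, amp=1.0, phase=0.0):
        t = np.arange(int(duration_s * fs)) / fs
        return ContinuousSignal(amp * np.sin(2 * np.pi * freq * t + phase), fs)

    return make
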