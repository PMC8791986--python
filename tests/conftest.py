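import numpy as np
import pytest

from mechanospectra import (KVMParams, SyntheticConfig, ToneSpec,
                            gen_tone_signal)


@pytest.fixture
def fast_sampling():
    """10 Hz sampling, 200 s — resolves tones up to a few Hz."""
    return SyntheticConfig(seed=11, sampling_interval=0.1, duration=200.0,
                           noise_sd=0.0)


@pytest.fixture
def tone_02hz(fast_sampling):
    return gen_tone_signal(ToneSpec(components=((0.2, 1.0, 0.0),)),
                           fast_sampling)


@pytest.fixture
def two_tone():
    """Dyadically separated pair: 0.5 Hz and 0.05 Hz, unit amplitudes."""
    cfg = SyntheticConfig(seed=12, sampling_interval=0.2, duration=200.0,
                          noise_sd=0.0)
    return gen_tone_signal(
        ToneSpec(components=((0.5, 1.0, 0.0), (0.05, 1.0, 0.0))), cfg)


@pytest.fixture
def default_params():
    return KVMParams()


@pytest.fixture
def trace_times():
    return np.arange(10.0, 1800.0 + 5.0, 10.0)
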