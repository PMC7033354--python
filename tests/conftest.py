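import numpy as np
import pytest

from backaverage import SynthConfig, generate

# Session-scoped synthetic recordings at the default study conditions
# (1000 Hz, 40 movements >= 5 s apart, burst SNR 10, EEG noise 10 uV,
# readiness potential -8 uV leading by 2 s), shared across test modules.


@pytest.fixture(scope="session")
def bp_synth():
    return generate(SynthConfig(mode="bp", seed=0))


@pytest.fixture(scope="session")
def null_synth():
    return generate(SynthConfig(mode="null", seed=0))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
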