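import numpy as np
import pytest

from ecgbispec.synth import SynthConfig, generate_record


@pytest.fixture(scope="session")
def default_record():
    """One class-A record at the default study conditions."""
    return generate_record(SynthConfig(seed=11), "A", 0)


@pytest.fixture(scope="session")
def clean_record():
    """Noise-free record (no power line, baseline or muscle noise)."""
    cfg = SynthConfig(powerline_amp=0.0, baseline_amp=0.0, muscle_noise_sd=0.0, seed=11)
    return generate_record(cfg, "A", 0)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
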