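import numpy as np
import pytest

from vesselnoise.synth import SynthConfig, generate_sample


@pytest.fixture(scope="session")
def synth_sample():
    """One default synthetic fundus sample (deterministic)."""
    return generate_sample(SynthConfig(seed=7), sample_id="fixture")


@pytest.fixture(scope="session")
def synth_sample_pair():
    """Two independent synthetic samples for train/test style checks."""
    a = generate_sample(SynthConfig(seed=21), sample_id="a")
    b = generate_sample(SynthConfig(seed=22), sample_id="b")
    return a, b


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
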