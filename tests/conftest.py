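import numpy as np
import pytest

from polyample.sequence_model import MarkovSequenceSpec, generate_sequence


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_sequence():
    """A modest i.i.d.-sign charge sequence for analyzer tests."""
    return generate_sequence(MarkovSequenceSpec(N=64, f=1.0, lam=0.0, seed=7))
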