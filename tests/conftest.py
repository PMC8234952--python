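from dataclasses import replace

import numpy as np
import pytest

from ecgtensor.synthetic import DEFAULT_BEAT, MorphLabel, synthesize_stream


@pytest.fixture
def clean_spec():
    """The default sinus template with every randomness source switched off."""
    return replace(DEFAULT_BEAT, noise_sd=0.0, period_jitter_sd=0.0)


@pytest.fixture
def noiseless_stream(clean_spec):
    return synthesize_stream(clean_spec, [MorphLabel.NORMAL] * 10, seed=7)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
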