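import numpy as np
import pytest
from dataclasses import replace

from hosemg.synthetic import AGGRESSIVE_SPEC, NORMAL_SPEC, SyntheticSpec


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def short_aggressive_spec():
    """2 s coupled-triad spec: enough segments to average, fast to analyze."""
    return replace(AGGRESSIVE_SPEC, duration=2.0, seed=7)


@pytest.fixture
def short_normal_spec():
    return replace(NORMAL_SPEC, duration=2.0, seed=7)
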