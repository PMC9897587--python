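import numpy as np
import pytest

from synctap.stimuli import (
    make_iso_repro_pattern,
    make_iso_sync_pattern,
    make_noniso_pattern,
    make_one_in_four_pattern,
    make_react_sequence,
)


@pytest.fixture
def iso_pattern():
    """Standard 1:1 synchronization pattern: 2 listen + 3 tap cycles at 500 ms."""
    return make_iso_sync_pattern(500.0, 3, 2)


@pytest.fixture
def repro_pattern():
    return make_iso_repro_pattern(500.0, 3, 2)


@pytest.fixture
def one_in_four_pattern():
    return make_one_in_four_pattern(500.0, 3, 2)


@pytest.fixture
def noniso_pattern():
    return make_noniso_pattern(500.0, 3, 2)


@pytest.fixture
def react_pattern():
    return make_react_sequence(60000.0, 200.0, 800.0, seed=7)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
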