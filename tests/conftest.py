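import numpy as np
import pytest

from replaykit import stimuli as st
from replaykit import synthetic as syn


@pytest.fixture(scope="session")
def blocks():
    return st.default_blocks()


@pytest.fixture(scope="session")
def pair_set():
    """All 12 ordered two-block compounds under on-top."""
    return syn.pair_stimulus_set()


@pytest.fixture(scope="session")
def stim12():
    """The 12 three-block task silhouettes."""
    return syn.default_stimulus_set()


@pytest.fixture(scope="session")
def triplets(pair_set):
    return st.enumerate_algebra_triplets(list(pair_set.values()))


@pytest.fixture
def cfg():
    return syn.GeneratorConfig(seed=7)


@pytest.fixture
def rng():
    return np.random.default_rng(7)
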