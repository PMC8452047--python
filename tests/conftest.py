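import numpy as np
import pytest

from ued.synthetic import make_lexicon


@pytest.fixture(scope="session")
def lexicons():
    """Synthetic dimensional + categorical lexicon pair (50x50 lattice)."""
    return make_lexicon()


@pytest.fixture(scope="session")
def vad_lexicon(lexicons):
    return lexicons[0]


@pytest.fixture(scope="session")
def emotion_lexicon(lexicons):
    return lexicons[1]


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
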