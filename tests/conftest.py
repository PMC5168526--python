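import numpy as np
import pytest

from vaxsent.corpus import CorpusParams, simulate_corpus


@pytest.fixture(scope="session")
def small_corpus():
    """2,000 tweets with moderate label signal; shared across read-only tests."""
    return simulate_corpus(CorpusParams(n_tweets=2000, seed=101, marker_strength=0.6))


@pytest.fixture(scope="session")
def separable_corpus():
    """60 tweets with fully label-specific vocabulary (marker_strength=1)."""
    return simulate_corpus(CorpusParams(n_tweets=60, seed=3, marker_strength=1.0))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
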