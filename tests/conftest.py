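import numpy as np
import pytest

from sentweet.embedding import TweetEmbedder
from sentweet.lexicon import Lexicon
from sentweet.preprocessing import TweetPreprocessor
from sentweet.synthetic import CorpusSpec, generate_corpus


@pytest.fixture(scope="session")
def bundled_lexicon() -> Lexicon:
    return Lexicon.bundled()


@pytest.fixture(scope="session")
def small_corpus():
    """120 synthetic tweets with strong planted signal, plus gold labels."""
    tweets, lexicon = generate_corpus(CorpusSpec(n_tweets=120, seed=5))
    return tweets, lexicon


@pytest.fixture(scope="session")
def small_sequences(small_corpus):
    tweets, _ = small_corpus
    return TweetPreprocessor().transform(tweets)


@pytest.fixture(scope="session")
def small_embedder(small_sequences) -> TweetEmbedder:
    return TweetEmbedder(seed=0, epochs=3).fit(small_sequences)


@pytest.fixture(scope="session")
def small_embeddings(small_embedder, small_sequences, small_corpus):
    tweets, _ = small_corpus
    X = small_embedder.transform(small_sequences)
    y = np.array([t.label for t in tweets])
    return X, y
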