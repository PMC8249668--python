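"""sentweet: three-class sentiment analysis of short informal health-related texts.

A full pipeline for classifying tweets about sport-related concussion as
positive (recognition of the injury risk), negative (disregard for it), or
neutral (no stance): deterministic text cleaning and normalization, a
four-signal 205-dimensional word embedding (POS index, 200-d skip-gram
vector, sentiment-lexicon grades, polarity-shift flag), seven small neural
classifiers, and vote-aggregation ensembles including a learned feed-forward
meta-learner, evaluated with prevalence-weighted precision/recall/F1.
"""

from .types import LABELS, Token, TokenSequence, Tweet

__version__ = "0.1.0"

__all__ = [
    "LABELS",
    "Token",
    "TokenSequence",
    "Tweet",
    "TweetPreprocessor",
    "TweetEmbedder",
    "NeuralTweetClassifier",
    "MajorityVoteEnsemble",
    "SoftVoteEnsemble",
    "MetaLearnerEnsemble",
]


def __getattr__(name):  # lazy imports keep `import sentweet` light
    if name == "TweetPreprocessor":
        from .preprocessing import TweetPreprocessor

        return TweetPreprocessor
    if name == "TweetEmbedder":
        from .embedding import TweetEmbedder

        return TweetEmbedder
    if name == "NeuralTweetClassifier":
        from .models import NeuralTweetClassifier

        return NeuralTweetClassifier
    if name in ("MajorityVoteEnsemble", "SoftVoteEnsemble", "MetaLearnerEnsemble"):
        from . import ensemble

        return getattr(ensemble, name)
    raise AttributeError(name)
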