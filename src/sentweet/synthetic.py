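"""Synthetic tweet corpora with planted sentiment structure.

Real annotated concussion-tweet corpora are not publicly deposited, so tests
and end-to-end runs use generated corpora that emulate their surface
statistics: three-class labels with priors 47% positive / 17% negative / 36%
neutral, tweet bodies assembled from a noise vocabulary, and the usual tweet
artifacts (hashtags, mentions, URLs, emoticons, elongations, leading ``RT``)
injected at configurable rates.

The sentiment signal is carried by planted lexicon words: a polar tweet
contains words of its own polarity class with probability
``signal_strength``, and with probability ``negation_rate`` a planted word is
rendered as a negation cue plus a word of the *opposite* polarity — so
recovering the label requires the polarity-shift rule, not just a bag of
lexicon words.  Neutral tweets draw only from the noise vocabulary and
neutral lexicon entries.  Generation is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import resources
from .lexicon import Lexicon
from .types import LABELS, TokenSequence, Tweet


@dataclass
class CorpusSpec:
    """Generator settings; defaults emulate the study corpus conditions."""

    n_tweets: int = 1000
    class_priors: tuple[float, float, float] = (0.47, 0.17, 0.36)
    signal_strength: float = 0.9
    noise_vocab_size: int = 150
    p_hashtag: float = 0.25
    p_mention: float = 0.30
    p_url: float = 0.15
    p_emoticon: float = 0.20
    p_elongation: float = 0.10
    p_retweet: float = 0.25
    negation_rate: float = 0.15
    mean_length: int = 12
    max_length: int = 24
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.class_priors) - 1.0) > 1e-9:
            raise ValueError("class priors must sum to 1")
        for name in ("signal_strength", "p_hashtag", "p_mention", "p_url",
                     "p_emoticon", "p_elongation", "p_retweet", "negation_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.n_tweets < 1 or self.mean_length < 2 or self.max_length < self.mean_length:
            raise ValueError("bad corpus size settings")

    def as_dict(self) -> dict:
        return {
            "n_tweets": self.n_tweets,
            "class_priors": list(self.class_priors),
            "signal_strength": self.signal_strength,
            "noise_vocab_size": self.noise_vocab_size,
            "p_hashtag": self.p_hashtag,
            "p_mention": self.p_mention,
            "p_url": self.p_url,
            "p_emoticon": self.p_emoticon,
            "p_elongation": self.p_elongation,
            "p_retweet": self.p_retweet,
            "negation_rate": self.negation_rate,
            "mean_length": self.mean_length,
            "max_length": self.max_length,
            "seed": self.seed,
        }


def lexicon_fixture() -> Lexicon:
    """The bundled ~200-entry sentiment lexicon (triplets sum to 1)."""
    return Lexicon.bundled()


def gazetteer_fixture() -> dict[str, str]:
    """The bundled gazetteer covering all seven entity classes."""
    return dict(resources.gazetteer())


def stoplist_fixture() -> frozenset[str]:
    """The bundled ~150-word stopword list."""
    return resources.stopwords()


def _surviving_lemma(word: str) -> str | None:
    """Lemma the word carries after the full normalization pipeline, if any."""
    from .preprocessing import preprocess_tweet

    seq = preprocess_tweet(word)
    if len(seq) != 1 or seq.tokens[0].is_special:
        return None
    return seq.tokens[0].lemma


def _word_pools(lexicon: Lexicon):
    """Planted-word pools, screened so each word round-trips through the
    normalization pipeline to a lexicon lemma of the intended polarity."""
    positive, negative, neutral = [], [], []
    for entry in sorted(lexicon, key=lambda e: e.lemma):
        lemma = _surviving_lemma(entry.lemma)
        if lemma is None:
            continue
        p, m, n = lexicon.lookup(lemma)
        if p >= 0.45 and p > m:
            positive.append(entry.lemma)
        elif m >= 0.45 and m > p:
            negative.append(entry.lemma)
        elif n >= 0.8:
            neutral.append(entry.lemma)
    return positive, negative, neutral


def _noise_vocabulary(size: int) -> list[str]:
    """Non-polar, non-stopword dictionary words, most frequent first; each is
    screened so its pipeline lemma carries no polar lexicon grade."""
    freq = resources.word_frequencies()
    lexicon = Lexicon.bundled()
    skip = resources.stopwords() | resources.negation_cues() | resources.clause_boundaries()
    words = []
    for w, _ in sorted(freq.items(), key=lambda kv: (-kv[1], kv[0])):
        if not w.isalpha() or len(w) <= 2 or w in skip:
            continue
        lemma = _surviving_lemma(w)
        if lemma is None:
            continue
        p, m, _n = lexicon.lookup(lemma)
        if max(p, m) >= 0.3:
            continue
        words.append(w)
        if len(words) >= size:
            break
    return words


_EMOTICON_CHOICES = (":)", ":(", ":D", ":'(", ";)", "<3", ":P", ":/")
_VOWELS = "aeiou"


def _elongate(word: str, rng: np.random.Generator) -> str:
    positions = [i for i, ch in enumerate(word) if ch in _VOWELS]
    if not positions:
        return word
    i = positions[rng.integers(len(positions))]
    return word[: i + 1] + word[i] * int(rng.integers(2, 6)) + word[i + 1 :]


def generate_corpus(spec: CorpusSpec) -> tuple[list[Tweet], Lexicon]:
    """Generate labeled tweets plus the planted lexicon.

    Returns the tweet list and the lexicon whose entries carry the planted
    sentiment signal (the bundled fixture lexicon: its triplets satisfy the
    sum-to-one normalization by construction).
    """
    rng = np.random.default_rng(spec.seed)
    lexicon = lexicon_fixture()
    pos_pool, neg_pool, neu_pool = _word_pools(lexicon)
    noise = _noise_vocabulary(spec.noise_vocab_size)
    priors = np.asarray(spec.class_priors)

    tweets: list[Tweet] = []
    for i in range(spec.n_tweets):
        label = LABELS[rng.choice(3, p=priors)]
        length = int(np.clip(rng.poisson(spec.mean_length), 4, spec.max_length))
        words = [noise[rng.integers(len(noise))] for _ in range(length)]

        # neutral lexicon words are common vocabulary: every tweet draws some,
        # so at signal 0 the three classes are generatively exchangeable and
        # only the polar plants below separate them
        for _ in range(int(rng.integers(1, 3))):
            words[rng.integers(len(words))] = neu_pool[rng.integers(len(neu_pool))]

        if label != "neutral" and rng.random() < spec.signal_strength:
            own, other = (pos_pool, neg_pool) if label == "positive" else (neg_pool, pos_pool)
            n_plant = int(rng.integers(1, 4))
            for _ in range(n_plant):
                slot = int(rng.integers(len(words)))
                if rng.random() < spec.negation_rate:
                    # surface flip: cue + opposite-polarity word, scope closed
                    # by a contrastive conjunction so plants stay independent
                    words[slot] = "not " + other[rng.integers(len(other))] + " but"
                else:
                    words[slot] = own[rng.integers(len(own))]

        if rng.random() < spec.p_elongation:
            slot = int(rng.integers(len(words)))
            if " " not in words[slot]:
                words[slot] = _elongate(words[slot], rng)
        if rng.random() < spec.p_hashtag:
            parts = [noise[rng.integers(len(noise))] for _ in range(int(rng.integers(1, 3)))]
            words.append("#" + "".join(p.capitalize() for p in parts))
        if rng.random() < spec.p_mention:
            words.insert(0, f"@user{rng.integers(1000)}")
        if rng.random() < spec.p_url:
            words.append("http://t.co/" + "".join(
                chr(97 + d) for d in rng.integers(0, 26, size=8)))
        if rng.random() < spec.p_emoticon:
            words.append(_EMOTICON_CHOICES[rng.integers(len(_EMOTICON_CHOICES))])
        if rng.random() < spec.p_retweet:
            words.insert(0, "RT")

        text = " ".join(words)
        while len(text) > 280:
            words = words[:-1]
            text = " ".join(words)
        tweets.append(Tweet(id=f"t{i:05d}", text=text, label=label,
                            is_retweet=words[0] == "RT"))
    return tweets, lexicon


def lexicon_argmax_baseline(sequences: list[TokenSequence], lexicon: Lexicon) -> list[str]:
    """Lexicon-only reference classifier.

    Sums the positivity/negativity grades over a tweet's tokens, swapping the
    two grades for tokens under an inverted polarity flag; predicts the polar
    class with the larger sum, or neutral when neither clearly dominates.
    """
    from .embedding import polarity_shift
    from .lexicon import coarse_pos

    out = []
    for seq in sequences:
        flags = polarity_shift(seq)
        s_plus = s_minus = 0.0
        for token, flag in zip(seq, flags):
            p, m, _ = lexicon.lookup(token.lemma, coarse_pos(token.pos_tag))
            if flag:
                p, m = m, p
            s_plus += p
            s_minus += m
        margin = s_plus - s_minus
        if abs(margin) < 0.2:
            out.append("neutral")
        else:
            out.append("positive" if margin > 0 else "negative")
    return out
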