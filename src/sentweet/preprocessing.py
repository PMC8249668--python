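"""Cleaning and normalization of raw tweet text into annotated token sequences.

The pipeline has two stages.  The *cleaning* stage operates on the raw string:
emoticons, mentions and URLs are encoded to category tokens (``<smile>``,
``<user>``, ``<url>``), hashtags are segmented into dictionary words behind a
``<hashtag>`` marker, elongated words ("helloooo") are trimmed against the
frequency dictionary, and the leading retweet marker plus residual punctuation
are stripped.  The *normalization* stage tokenizes, POS-tags, lemmatizes,
masks named entities onto seven class tags, and removes stopwords.

Stage order within cleaning: URL/mention/emoticon encoding runs first so that
later steps (hashtag segmentation, elongation trimming, punctuation removal)
can never corrupt a URL or emoticon; the leading-``RT``/punctuation strip runs
last so encodings are already in place and pass through intact.  Applying the
cleaning stage to its own output is a no-op.
"""

from __future__ import annotations

import math
import re

from sklearn.base import BaseEstimator, TransformerMixin

from . import postag, resources
from .types import ENTITY_CLASSES, Token, TokenSequence, Tweet

_URL_RE = re.compile(r"(?:https?://\S+|www\.\S+|\b[a-z0-9.\-]+\.(?:com|org|net|co|ly|io)/\S+)")
_MENTION_RE = re.compile(r"@\w+")
_HASHTAG_RE = re.compile(r"#(\w*)")
_ELONGATION_RE = re.compile(r"(\w)\1{2,}")
_WS_RE = re.compile(r"\s+")


def _emoticon_regex() -> re.Pattern:
    patterns = sorted(resources.emoticon_table(), key=len, reverse=True)
    body = "|".join(re.escape(p) for p in patterns)
    return re.compile(rf"(?:(?<=\s)|^)(?:{body})(?=\s|$)")


_EMOTICON_RE = None  # built lazily; depends on the bundled table


def encode_special_words(text: str) -> str:
    """Replace URLs, ``@user`` mentions, and emoticons by their category tokens."""
    global _EMOTICON_RE
    if _EMOTICON_RE is None:
        _EMOTICON_RE = _emoticon_regex()
    table = resources.emoticon_table()
    text = _URL_RE.sub("<url>", text)
    text = _MENTION_RE.sub("<user>", text)
    text = _EMOTICON_RE.sub(lambda m: table[m.group(0)], text)
    return text


def _camel_chunks(body: str) -> list[str]:
    """Split a hashtag body at camel-case and letter/digit boundaries (free splits)."""
    chunks = re.findall(r"[A-Z]+(?![a-z])|[A-Z][a-z]*|[a-z]+|\d+", body)
    return [c.lower() for c in chunks]


def segment_words(chunk: str, frequencies: dict[str, float] | None = None) -> list[str]:
    """Maximum-likelihood segmentation of ``chunk`` into dictionary words.

    Dynamic programming over split points maximizing the summed log unigram
    frequency; substrings absent from the dictionary pay a per-word plus
    per-character penalty, so unknown material is kept in one piece.
    """
    if frequencies is None:
        frequencies = resources.word_frequencies()
    if not chunk:
        return []
    n = len(chunk)
    log_unknown_base = math.log(1e-8)
    per_char_penalty = math.log(10)

    def score(word: str) -> float:
        p = frequencies.get(word)
        if p is not None:
            return math.log(p)
        return log_unknown_base - per_char_penalty * len(word)

    best = [(-math.inf, 0)] * (n + 1)
    best[0] = (0.0, 0)
    for i in range(1, n + 1):
        for j in range(max(0, i - 24), i):
            s = best[j][0] + score(chunk[j:i])
            if s > best[i][0]:
                best[i] = (s, j)
    words = []
    i = n
    while i > 0:
        j = best[i][1]
        words.append(chunk[j:i])
        i = j
    return words[::-1]


def process_hashtags(text: str, frequencies: dict[str, float] | None = None) -> str:
    """``#CamelCaseOrConcatenated`` -> ``<hashtag>`` plus segmented lowercase words."""

    def repl(match: re.Match) -> str:
        body = match.group(1)
        words: list[str] = []
        for chunk in _camel_chunks(body):
            if chunk.isdigit():
                words.append(chunk)
            else:
                words.extend(segment_words(chunk, frequencies))
        return " ".join(["<hashtag>", *words]).rstrip()

    return _HASHTAG_RE.sub(repl, text)


def trim_elongation(token: str, frequencies: dict[str, float] | None = None) -> str:
    """Reduce character runs of length >= 3 to 2, or to 1 if only that form
    is in the dictionary ("helloooo" -> "hello")."""
    if not _ELONGATION_RE.search(token):
        return token
    if frequencies is None:
        frequencies = resources.word_frequencies()
    two_run = _ELONGATION_RE.sub(r"\1\1", token)
    if two_run.lower() in frequencies:
        return two_run
    one_run = _ELONGATION_RE.sub(r"\1", token)
    if one_run.lower() in frequencies:
        return one_run
    return two_run


# number-bearing patterns protected from punctuation stripping because the
# entity masker recognizes them (money, percent, time, date)
_PROTECTED_RE = re.compile(r"\$\d+(?:\.\d+)?|\d+(?:\.\d+)?%|\d{1,2}:\d{2}(?:am|pm)?|\d{1,2}/\d{1,2}/\d{2,4}")
_STRIP_RE = re.compile(r"[^\w\s<>'\x00]|(?<!\w)'|'(?!\w)")


def strip_retweet_and_specials(text: str) -> tuple[str, bool]:
    """Drop one leading ``RT`` marker (flagging the tweet as a retweet) and all
    punctuation that is not part of an encoding, a contraction, or a protected
    money/percent/time/date pattern."""
    is_retweet = False
    stripped = text.lstrip()
    if stripped == "RT" or stripped.startswith("RT "):
        text = stripped[2:]
        is_retweet = True
    protected: list[str] = []

    def stash(match: re.Match) -> str:
        protected.append(match.group(0))
        return f"\x00{len(protected) - 1}\x00"

    text = _PROTECTED_RE.sub(stash, text)
    text = _STRIP_RE.sub(" ", text)
    text = re.sub(r"\x00(\d+)\x00", lambda m: protected[int(m.group(1))], text)
    return _WS_RE.sub(" ", text).strip(), is_retweet


def clean_tweet(text: str, frequencies: dict[str, float] | None = None) -> tuple[str, bool]:
    """Full cleaning stage: encodings, hashtags, elongation, RT/punctuation strip."""
    text = encode_special_words(text)
    text = process_hashtags(text, frequencies)
    tokens = [
        t if postag.is_special_token(t) else trim_elongation(t, frequencies)
        for t in text.split()
    ]
    return strip_retweet_and_specials(" ".join(tokens))


_TOKEN_RE = re.compile(
    r"<[a-z3/]+>"
    r"|\$\d+(?:\.\d+)?"
    r"|\d+(?:\.\d+)?%"
    r"|\d{1,2}:\d{2}(?:am|pm)?"
    r"|\d{1,2}/\d{1,2}/\d{2,4}"
    r"|[A-Za-z]+n't"
    r"|[A-Za-z0-9]+(?:'[A-Za-z]+)?"
)


def tokenize(text: str) -> list[str]:
    """Tokenize cleaned text, splitting ``n't`` contractions into two tokens."""
    tokens: list[str] = []
    for tok in _TOKEN_RE.findall(text):
        if tok.lower().endswith("n't") and len(tok) > 3:
            tokens.extend([tok[:-3], "n't"])
        else:
            tokens.append(tok)
    return tokens


def tokenize_and_lemmatize(text: str) -> list[Token]:
    """Tokenize cleaned text, POS-tag on surface forms (case is informative),
    then store the tag-conditioned lowercase lemma."""
    surfaces = tokenize(text)
    tags = postag.pos_tag(surfaces)
    out = []
    for surface, tag in zip(surfaces, tags):
        special = tag == postag.SPECIAL_POS
        out.append(
            Token(
                surface=surface,
                lemma=postag.lemmatize(surface, tag),
                pos_tag=tag,
                is_special=special,
            )
        )
    return out


_MONEY_RE = re.compile(r"^\$\d+(\.\d+)?$")
_PERCENT_RE = re.compile(r"^\d+(\.\d+)?%$")
_TIME_RE = re.compile(r"^(\d{1,2}:\d{2}(am|pm)?|\d{1,2}(am|pm))$")
_DATE_RE = re.compile(r"^(\d{1,2}/\d{1,2}/\d{2,4}|(19|20)\d{2})$")

_PATTERN_ENTITIES = (
    (_MONEY_RE, "money"),
    (_PERCENT_RE, "percent"),
    (_TIME_RE, "time"),
    (_DATE_RE, "date"),
)


def mask_entities(tokens: list[Token], gazetteer: dict[str, str] | None = None) -> list[Token]:
    """Replace recognized entity tokens by one of the seven class tags.

    Money, percent, date and time are recognized by surface patterns; person,
    location and organization (plus literal date/time/... words) by gazetteer
    lookup on the lemma.
    """
    if gazetteer is None:
        gazetteer = resources.gazetteer()
    out = []
    for token in tokens:
        if token.is_special:
            out.append(token)
            continue
        entity = None
        for pattern, cls in _PATTERN_ENTITIES:
            if pattern.match(token.surface):
                entity = cls
                break
        if entity is None:
            entity = gazetteer.get(token.lemma)
        if entity is not None and entity in ENTITY_CLASSES:
            out.append(token.with_entity(entity, f"<{entity}>"))
        else:
            out.append(token)
    return out


def remove_stopwords(
    tokens: list[Token], stoplist: frozenset[str] | set[str] | None = None, source_id: str = ""
) -> TokenSequence:
    if stoplist is None:
        stoplist = resources.stopwords()
    kept = [t for t in tokens if t.lemma not in stoplist]
    return TokenSequence(tokens=kept, source_id=source_id)


def preprocess_tweet(
    text: str,
    source_id: str = "",
    frequencies: dict[str, float] | None = None,
    gazetteer: dict[str, str] | None = None,
    stoplist: frozenset[str] | None = None,
) -> TokenSequence:
    """Run the full cleaning + normalization pipeline on one raw tweet."""
    cleaned, _ = clean_tweet(text, frequencies)
    tokens = tokenize_and_lemmatize(cleaned)
    tokens = mask_entities(tokens, gazetteer)
    return remove_stopwords(tokens, stoplist, source_id=source_id)


class TweetPreprocessor(BaseEstimator, TransformerMixin):
    """Stateless transformer: raw tweet texts -> annotated token sequences.

    Accepts a list of strings or :class:`~sentweet.types.Tweet` objects and
    returns a list of :class:`~sentweet.types.TokenSequence`.  All resources
    (frequency dictionary, gazetteer, stoplist) default to the bundled
    versioned fixtures, so the transform is deterministic.
    """

    def __init__(self, frequencies=None, gazetteer=None, stoplist=None):
        self.frequencies = frequencies
        self.gazetteer = gazetteer
        self.stoplist = stoplist

    def fit(self, X, y=None):
        self.n_features_in_ = 1
        return self

    def transform(self, X) -> list[TokenSequence]:
        out = []
        for i, item in enumerate(X):
            if isinstance(item, Tweet):
                text, source_id = item.text, item.id
            else:
                text, source_id = str(item), str(i)
            out.append(
                preprocess_tweet(
                    text,
                    source_id=source_id,
                    frequencies=self.frequencies,
                    gazetteer=self.gazetteer,
                    stoplist=self.stoplist,
                )
            )
        return out
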