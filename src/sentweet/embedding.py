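"""Four-signal word vectorization and assembly of the fixed-size tweet matrix.

Every token is embedded as a 205-dimensional vector partitioned as
``[1 | 200 | 3 | 1]``:

* column 0 — Penn Treebank POS tag index, an integer 1..36 in alphabetical
  tag order (0 for special tokens, which carry no POS);
* columns 1..200 — the 200-d skip-gram semantic vector (zeros when out of
  vocabulary);
* columns 201..203 — the sentiment-lexicon grades (positivity, negativity,
  neutrality), a probability triplet summing to 1;
* column 204 — the polarity-shift flag: 1 when the token sits inside the
  scope of a negation cue ("I am *not* happy"), else 0.

Token vectors are stacked into an ``n x 205`` matrix per tweet with a fixed
token budget ``n`` (default 24): longer sequences are truncated from the end,
shorter ones zero-padded, with a boolean mask marking real rows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from . import resources
from .lexicon import Lexicon, coarse_pos
from .postag import PENN_TAGS, SPECIAL_POS
from .types import TokenSequence
from .word2vec import WordVectorModel, train_semantic_vectors

EMBEDDING_DIM = 205
SEMANTIC_DIM = 200
#: default fixed token budget (padded/truncated tweet length)
DEFAULT_TOKEN_BUDGET = 24

_POS_INDEX = {tag: i + 1 for i, tag in enumerate(sorted(PENN_TAGS))}


def pos_index(tag: str) -> int:
    """Map a Penn Treebank tag to its index in 1..36 (alphabetical order);
    the special-token marker maps to 0."""
    if tag == SPECIAL_POS:
        return 0
    try:
        return _POS_INDEX[tag]
    except KeyError:
        raise ValueError(f"unknown Penn Treebank tag: {tag!r}") from None


def polarity_shift(tokens: TokenSequence | list) -> list[int]:
    """Per-token polarity flag: 1 = inverted, 0 = normal.

    Tokens following a negation cue up to the next clause boundary (a
    contrastive conjunction; sentence punctuation is already stripped during
    cleaning) are flagged inverted.  A second cue inside one scope restores
    normal polarity, so "not not fine" leaves "fine" normal.
    """
    cues = resources.negation_cues()
    boundaries = resources.clause_boundaries()
    flags = []
    inverted = False
    for token in tokens:
        lemma = getattr(token, "lemma", token)
        if lemma in boundaries:
            inverted = False
            flags.append(0)
        elif lemma in cues:
            inverted = not inverted
            flags.append(1 if inverted else 0)
        else:
            flags.append(1 if inverted else 0)
    return flags


def embed_tweet(
    tokens: TokenSequence,
    model: WordVectorModel,
    lexicon: Lexicon,
    n: int = DEFAULT_TOKEN_BUDGET,
) -> "EmbeddedTweet":
    """Embed one normalized tweet as an (n, 205) matrix plus padding mask."""
    if n < 1:
        raise ValueError("token budget n must be >= 1")
    matrix = np.zeros((n, EMBEDDING_DIM))
    mask = np.zeros(n, dtype=bool)
    flags = polarity_shift(tokens)
    for row, (token, flag) in enumerate(zip(tokens, flags)):
        if row >= n:
            break
        matrix[row, 0] = pos_index(token.pos_tag)
        matrix[row, 1 : 1 + SEMANTIC_DIM] = model.vector(token.lemma)
        matrix[row, 201:204] = lexicon.lookup(token.lemma, coarse_pos(token.pos_tag))
        matrix[row, 204] = flag
        mask[row] = True
    return EmbeddedTweet(matrix=matrix, mask=mask, n=n)


@dataclass
class EmbeddedTweet:
    """Fixed-size numeric representation of one tweet."""

    matrix: np.ndarray
    mask: np.ndarray
    n: int = DEFAULT_TOKEN_BUDGET

    def __post_init__(self) -> None:
        if self.matrix.shape != (self.n, EMBEDDING_DIM):
            raise ValueError(f"matrix must be ({self.n}, {EMBEDDING_DIM})")


class TweetEmbedder(BaseEstimator, TransformerMixin):
    """Transformer: token sequences -> stacked (N, n, 205) embedding tensor.

    ``fit`` trains the skip-gram semantic vectors on the training token
    sequences (deterministic given ``seed``); ``transform`` assembles the
    per-tweet matrices.  The sentiment lexicon defaults to the bundled
    fixture.  Skip-gram hyperparameters (window 5, min_count 2, 5 negative
    samples, 10 epochs) are exposed as parameters.
    """

    def __init__(
        self,
        n: int = DEFAULT_TOKEN_BUDGET,
        dim: int = SEMANTIC_DIM,
        window: int = 5,
        min_count: int = 2,
        negative: int = 5,
        epochs: int = 10,
        seed: int = 0,
        lexicon: Lexicon | None = None,
    ):
        self.n = n
        self.dim = dim
        self.window = window
        self.min_count = min_count
        self.negative = negative
        self.epochs = epochs
        self.seed = seed
        self.lexicon = lexicon

    def fit(self, X: list[TokenSequence], y=None):
        if self.dim != SEMANTIC_DIM:
            raise ValueError(f"semantic dimension is fixed at {SEMANTIC_DIM}")
        self.model_ = train_semantic_vectors(
            X,
            dim=self.dim,
            window=self.window,
            min_count=self.min_count,
            negative=self.negative,
            epochs=self.epochs,
            seed=self.seed,
        )
        self.lexicon_ = self.lexicon if self.lexicon is not None else Lexicon.bundled()
        return self

    def transform(self, X: list[TokenSequence]) -> np.ndarray:
        embedded = [embed_tweet(seq, self.model_, self.lexicon_, n=self.n) for seq in X]
        return np.stack([e.matrix for e in embedded]) if embedded else np.zeros(
            (0, self.n, EMBEDDING_DIM)
        )

    def transform_with_masks(self, X: list[TokenSequence]):
        embedded = [embed_tweet(seq, self.model_, self.lexicon_, n=self.n) for seq in X]
        matrices = np.stack([e.matrix for e in embedded])
        masks = np.stack([e.mask for e in embedded])
        return matrices, masks
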