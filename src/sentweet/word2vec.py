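"""Skip-gram word vectors with negative sampling (SGNS), in plain numpy.

Trains 200-dimensional distributed word representations on the normalized
corpus: each center word predicts the words in a symmetric context window,
against ``negative`` noise words drawn from the unigram distribution raised
to the 3/4 power.  Training is single-threaded and fully seeded, so two runs
with the same corpus and seed produce identical vectors.

Out-of-vocabulary lookups (including words dropped by ``min_count``) return
the zero vector, which downstream models distinguish from real embeddings via
the padding mask.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .types import TokenSequence


def _expit(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class WordVectorModel:
    """Vocabulary plus a |V| x dim matrix of input vectors."""

    def __init__(self, vocabulary: dict[str, int], vectors: np.ndarray):
        if vectors.ndim != 2 or len(vocabulary) != vectors.shape[0]:
            raise ValueError("vocabulary and vector matrix disagree")
        self.vocabulary = vocabulary
        self.vectors = vectors
        self.dim = vectors.shape[1]

    def __contains__(self, word: str) -> bool:
        return word in self.vocabulary

    def vector(self, word: str) -> np.ndarray:
        idx = self.vocabulary.get(word)
        if idx is None:
            return np.zeros(self.dim, dtype=self.vectors.dtype)
        return self.vectors[idx]

    def cosine(self, a: str, b: str) -> float:
        va, vb = self.vector(a), self.vector(b)
        na, nb = np.linalg.norm(va), np.linalg.norm(vb)
        if na == 0 or nb == 0:
            return 0.0
        return float(va @ vb / (na * nb))

    def save(self, prefix: str | Path) -> None:
        """Serialize as vocabulary JSON + dense matrix with shape header (.npy)."""
        prefix = Path(prefix)
        prefix.parent.mkdir(parents=True, exist_ok=True)
        with open(prefix.with_suffix(".vocab.json"), "w", encoding="utf-8") as fh:
            json.dump(self.vocabulary, fh)
        np.save(prefix.with_suffix(".vectors.npy"), self.vectors)

    @classmethod
    def load(cls, prefix: str | Path) -> "WordVectorModel":
        prefix = Path(prefix)
        with open(prefix.with_suffix(".vocab.json"), encoding="utf-8") as fh:
            vocabulary = json.load(fh)
        vectors = np.load(prefix.with_suffix(".vectors.npy"))
        return cls(vocabulary, vectors)


def _as_lemma_lists(corpus) -> list[list[str]]:
    out = []
    for seq in corpus:
        if isinstance(seq, TokenSequence):
            out.append(seq.lemmas())
        else:
            out.append(list(seq))
    return out


def train_semantic_vectors(
    corpus,
    dim: int = 200,
    window: int = 5,
    min_count: int = 2,
    negative: int = 5,
    epochs: int = 10,
    lr: float = 0.025,
    seed: int = 0,
    batch_size: int = 1024,
) -> WordVectorModel:
    """Train SGNS vectors on a corpus of token sequences (or lemma lists)."""
    sentences = _as_lemma_lists(corpus)
    if not sentences or not any(sentences):
        raise ValueError("empty corpus")

    counts: dict[str, int] = {}
    for sent in sentences:
        for w in sent:
            counts[w] = counts.get(w, 0) + 1
    vocab_words = sorted(w for w, c in counts.items() if c >= min_count)
    vocabulary = {w: i for i, w in enumerate(vocab_words)}
    V = len(vocabulary)
    rng = np.random.default_rng(seed)
    if V == 0:
        return WordVectorModel({}, np.zeros((0, dim)))

    # center/context training pairs from the symmetric window
    centers, contexts = [], []
    for sent in sentences:
        idx = [vocabulary[w] for w in sent if w in vocabulary]
        for i, c in enumerate(idx):
            lo, hi = max(0, i - window), min(len(idx), i + window + 1)
            for j in range(lo, hi):
                if j != i:
                    centers.append(c)
                    contexts.append(idx[j])
    if not centers:
        return WordVectorModel(vocabulary, np.zeros((V, dim)))
    centers = np.asarray(centers, dtype=np.int64)
    contexts = np.asarray(contexts, dtype=np.int64)

    # noise distribution: unigram ** 0.75
    freq = np.zeros(V)
    for w, i in vocabulary.items():
        freq[i] = counts[w]
    noise = freq**0.75
    noise /= noise.sum()

    W_in = (rng.random((V, dim)) - 0.5) / dim
    W_out = np.zeros((V, dim))

    n_pairs = len(centers)
    for epoch in range(epochs):
        order = rng.permutation(n_pairs)
        alpha = lr * max(1.0 - epoch / epochs, 0.1)
        for start in range(0, n_pairs, batch_size):
            sel = order[start : start + batch_size]
            c, o = centers[sel], contexts[sel]
            neg = rng.choice(V, size=(len(sel), negative), p=noise)
            vc = W_in[c]  # (B, dim)
            targets = np.concatenate([o[:, None], neg], axis=1)  # (B, 1+k)
            vt = W_out[targets]  # (B, 1+k, dim)
            score = _expit(np.einsum("bd,bkd->bk", vc, vt))
            label = np.zeros_like(score)
            label[:, 0] = 1.0
            err = alpha * (label - score)  # (B, 1+k)
            grad_c = np.einsum("bk,bkd->bd", err, vt)
            grad_t = err[:, :, None] * vc[:, None, :]
            np.add.at(W_out, targets.ravel(), grad_t.reshape(-1, dim))
            np.add.at(W_in, c, grad_c)

    return WordVectorModel(vocabulary, W_in)
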