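"""Four-signal word vectorization: POS index, lexicon grades, polarity, shapes."""

import itertools

import numpy as np
import pytest

from sentweet.embedding import (
    EMBEDDING_DIM,
    TweetEmbedder,
    embed_tweet,
    polarity_shift,
    pos_index,
)
from sentweet.lexicon import Lexicon, LexiconEntry, lexicon_lookup
from sentweet.postag import PENN_TAGS
from sentweet.preprocessing import preprocess_tweet, tokenize_and_lemmatize
from sentweet.types import Token, TokenSequence
from sentweet.word2vec import WordVectorModel, train_semantic_vectors


class TestPosIndex:
    def test_bijection_onto_1_to_36(self):
        values = [pos_index(tag) for tag in PENN_TAGS]
        assert sorted(values) == list(range(1, 37))

    def test_alphabetical_anchors(self):
        ordered = sorted(PENN_TAGS)
        assert pos_index(ordered[0]) == 1
        assert pos_index(ordered[-1]) == 36

    def test_special_marker_maps_to_zero(self):
        assert pos_index("SPECIAL") == 0

    def test_unknown_tag_is_named_in_error(self):
        with pytest.raises(ValueError, match="XYZ"):
            pos_index("XYZ")


class TestLexicon:
    def test_every_bundled_triplet_sums_to_one(self, bundled_lexicon):
        for entry in bundled_lexicon:
            assert abs(sum(entry.triplet) - 1.0) <= 1e-9

    def test_unseen_word_falls_back_to_neutral(self, bundled_lexicon):
        assert lexicon_lookup("zzxq", "n", bundled_lexicon) == (0.0, 0.0, 1.0)

    def test_fixture_roundtrip(self, tmp_path):
        lex = Lexicon([LexiconEntry("good", "a", 0.75, 0.0, 0.25)])
        lex.to_tsv(tmp_path / "lex.tsv")
        again = Lexicon.from_tsv(tmp_path / "lex.tsv")
        assert again.lookup("good", "a") == (0.75, 0.0, 0.25)

    def test_malformed_entry_rejected_at_load(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("good\ta\t0.8\t0.4\t0.2\n")
        with pytest.raises(ValueError, match="sum"):
            Lexicon.from_tsv(path)

    def test_negative_grade_rejected(self):
        with pytest.raises(ValueError):
            LexiconEntry("odd", "a", 1.2, -0.4, 0.2)


def _words(text):
    return TokenSequence(tokens=tokenize_and_lemmatize(text))


class TestPolarityShift:
    def test_negated_word_is_inverted(self):
        seq = _words("I am not happy")
        flags = dict(zip(seq.lemmas(), polarity_shift(seq)))
        assert flags["happy"] == 1

    def test_plain_word_is_normal(self):
        seq = _words("I am happy")
        flags = dict(zip(seq.lemmas(), polarity_shift(seq)))
        assert flags["happy"] == 0

    def test_double_negation_restores_normal(self):
        seq = _words("not not fine")
        assert polarity_shift(seq)[-1] == 0

    def test_scope_ends_at_contrastive_conjunction(self):
        seq = _words("not bad but scary stuff")
        flags = dict(zip(seq.lemmas(), polarity_shift(seq)))
        assert flags["bad"] == 1 and flags["scary"] == 0

    @pytest.mark.parametrize("n_cues", [0, 1, 2, 3])
    def test_exhaustive_truth_table_up_to_three_cues(self, n_cues):
        """Parity of preceding cues decides the flag (no boundaries present)."""
        words = ["not"] * n_cues + ["fine"]
        seq = TokenSequence(tokens=[Token(w, w, "JJ") for w in words])
        assert polarity_shift(seq)[-1] == n_cues % 2


class TestWordVectors:
    def test_dimension_and_oov_contract(self):
        corpus = [["game", "over", "game", "over"]] * 3
        model = train_semantic_vectors(corpus, dim=200, min_count=2, epochs=1, seed=0)
        assert model.vector("game").shape == (200,)
        assert model.vector("game").any()  # trained vector is non-zero
        assert np.all(model.vector("neverseen") == 0.0)

    def test_empty_corpus_is_an_error(self):
        with pytest.raises(ValueError):
            train_semantic_vectors([], seed=0)

    def test_same_seed_reproduces_vectors(self):
        corpus = [["a", "b", "c", "a", "b"]] * 20
        m1 = train_semantic_vectors(corpus, epochs=2, min_count=1, seed=3)
        m2 = train_semantic_vectors(corpus, epochs=2, min_count=1, seed=3)
        assert np.array_equal(m1.vectors, m2.vectors)

    @pytest.mark.parametrize("seed", range(5))
    def test_shared_contexts_increase_cosine(self, seed):
        """Words A and B share contexts; C never does: cos(A,B) > cos(A,C)."""
        rng = np.random.default_rng(seed)
        contexts = [f"w{k}" for k in range(8)]
        others = [f"v{k}" for k in range(8)]
        corpus = []
        for _ in range(200):
            target = "aa" if rng.random() < 0.5 else "bb"
            corpus.append([contexts[rng.integers(8)], target, contexts[rng.integers(8)]])
            corpus.append([others[rng.integers(8)], "cc", others[rng.integers(8)]])
        model = train_semantic_vectors(corpus, min_count=1, epochs=10, seed=seed)
        assert model.cosine("aa", "bb") > model.cosine("aa", "cc")

    def test_serialization_roundtrip(self, tmp_path):
        corpus = [["x", "y", "x", "y"]] * 5
        model = train_semantic_vectors(corpus, min_count=1, epochs=1, seed=0)
        model.save(tmp_path / "wv")
        again = WordVectorModel.load(tmp_path / "wv")
        assert again.vocabulary == model.vocabulary
        assert np.array_equal(again.vectors, model.vectors)


class TestEmbedTweet:
    def test_output_shape_is_token_budget_by_205(self, small_embedder):
        seq = preprocess_tweet("the game is not over for Bob")
        emb = embed_tweet(seq, small_embedder.model_, small_embedder.lexicon_, n=24)
        assert emb.matrix.shape == (24, 205)

    def test_empty_sequence_gives_all_zero_matrix(self, small_embedder):
        emb = embed_tweet(TokenSequence(), small_embedder.model_, small_embedder.lexicon_, n=10)
        assert not emb.matrix.any()
        assert not emb.mask.any()

    def test_rows_equal_hand_concatenated_vectors(self):
        """Three tokens with known lexicon entries embed to the exact
        [pos | semantic | grades | polarity] concatenation."""
        lexicon = Lexicon([
            LexiconEntry("good", "a", 0.75, 0.0, 0.25),
            LexiconEntry("bad", "a", 0.1, 0.7, 0.2),
        ])
        vocab = {"good": 0, "bad": 1, "not": 2}
        vectors = np.arange(600, dtype=float).reshape(3, 200)
        model = WordVectorModel(vocab, vectors)
        tokens = TokenSequence(tokens=[
            Token("good", "good", "JJ"),
            Token("not", "not", "RB"),
            Token("bad", "bad", "JJ"),
        ])
        emb = embed_tweet(tokens, model, lexicon, n=4)
        row0 = np.concatenate([[pos_index("JJ")], vectors[0], [0.75, 0.0, 0.25], [0]])
        row1 = np.concatenate([[pos_index("RB")], vectors[2], [0.0, 0.0, 1.0], [1]])
        row2 = np.concatenate([[pos_index("JJ")], vectors[1], [0.1, 0.7, 0.2], [1]])
        assert np.array_equal(emb.matrix[0], row0)
        assert np.array_equal(emb.matrix[1], row1)  # the cue itself is inverted
        assert np.array_equal(emb.matrix[2], row2)
        assert not emb.matrix[3].any() and not emb.mask[3]

    def test_column_partition_invariants(self, small_embedder, small_sequences):
        X, masks = small_embedder.transform_with_masks(small_sequences[:40])
        real = X[masks]
        assert real[:, 0].min() >= 0 and real[:, 0].max() <= 36
        assert np.allclose(real[:, 201:204].sum(axis=1), 1.0)
        assert set(np.unique(real[:, 204])) <= {0.0, 1.0}

    def test_truncation_padding_duality(self, small_embedder):
        seq = preprocess_tweet(
            "the coach and the doctor watch the game while the player takes a hit "
            "to the head and leaves the ice for the hospital after the match"
        )
        assert len(seq) > 6
        truncated = TokenSequence(tokens=seq.tokens[:6], source_id=seq.source_id)
        full = embed_tweet(seq, small_embedder.model_, small_embedder.lexicon_, n=6)
        trunc = embed_tweet(truncated, small_embedder.model_, small_embedder.lexicon_, n=6)
        assert np.array_equal(full.matrix, trunc.matrix)

    def test_embedder_transform_stacks(self, small_embedder, small_sequences):
        X = small_embedder.transform(small_sequences[:7])
        assert X.shape == (7, 24, EMBEDDING_DIM)
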