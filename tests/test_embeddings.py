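"""Skip-gram training, subsampling, similarity queries."""
import io
import itertools

import numpy as np
import pytest

from kgwalk import (EmbeddingSet, SkipgramParams, Walk, build_vocab,
                    cosine_similarity, nearest_neighbors, sgns_gradients,
                    sgns_objective, subsample_discard_prob, train_skipgram)
from kgwalk.embeddings import mean_pair_objective
from kgwalk.errors import (DegenerateVocabularyError, EntityNotFoundError,
                           InvalidArgumentError, UndefinedSimilarityError)
from kgwalk.walks import WalkCorpus


def _corpus(lines):
    walks = [Walk(tuple(line.split())) for line in lines]
    return WalkCorpus(walks=walks, walk_length=1, walks_per_node=1,
                      start_set=tuple(w.tokens[0] for w in walks), seed=0)


def _two_clique_corpus(rng, n_walks=120, length=6):
    """Tokens a1..a5 co-walked, b1..b5 co-walked, never mixed."""
    lines = []
    for i in range(n_walks):
        group, label = ("a", "r") if i % 2 == 0 else ("b", "s")
        toks = [f"{group}{rng.integers(1, 6)}"]
        for _ in range(length):
            toks += [label, f"{group}{rng.integers(1, 6)}"]
        lines.append(" ".join(toks))
    return _corpus(lines)


class TestVocabulary:
    def test_single_walk_frequencies(self):
        vocab = build_vocab(_corpus(["a r b"]))
        assert vocab.total == 3
        for tok in ("a", "r", "b"):
            assert vocab.frequency(tok) == pytest.approx(1 / 3)

    def test_counts_match_independent_recount(self):
        rng = np.random.default_rng(0)
        corpus = _two_clique_corpus(rng)
        vocab = build_vocab(corpus)
        brute = {}
        for walk in corpus.walks:
            for tok in walk.tokens:
                brute[tok] = brute.get(tok, 0) + 1
        assert {t: int(vocab.counts[vocab.index[t]]) for t in vocab.tokens} \
            == brute
        assert len(vocab) <= 10 + 2  # token universe: nodes + labels

    def test_empty_corpus_rejected(self):
        with pytest.raises(InvalidArgumentError):
            build_vocab(_corpus([]))


class TestSubsampling:
    @pytest.mark.parametrize("f,t,expected", [
        (1e-3, 1e-3, 0.0),
        (4e-3, 1e-3, 0.5),
        (5e-4, 1e-3, 0.0),
    ])
    def test_discard_probability(self, f, t, expected):
        assert subsample_discard_prob(f, t) == pytest.approx(expected)

    def test_invalid_inputs(self):
        with pytest.raises(InvalidArgumentError):
            subsample_discard_prob(0.0, 1e-3)
        with pytest.raises(InvalidArgumentError):
            subsample_discard_prob(0.5, 0.0)


class TestObjectiveAndGradient:
    def test_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(7)
        v_in = rng.normal(size=16)
        v_ctx = rng.normal(size=16)
        v_negs = rng.normal(size=(5, 16))
        g_in, g_ctx, g_negs = sgns_gradients(v_in, v_ctx, v_negs)
        eps = 1e-6

        def fd(vec, grad):
            for idx in np.ndindex(vec.shape):
                plus, minus = vec.copy(), vec.copy()
                plus[idx] += eps
                minus[idx] -= eps
                num = (_obj(v_in, v_ctx, v_negs, vec, plus)
                       - _obj(v_in, v_ctx, v_negs, vec, minus)) / (2 * eps)
                assert abs(num - grad[idx]) <= 1e-5 * max(1.0, abs(grad[idx]))

        def _obj(vi, vc, vn, target, replacement):
            if target is vi:
                return sgns_objective(replacement, vc, vn)
            if target is vc:
                return sgns_objective(vi, replacement, vn)
            return sgns_objective(vi, vc, replacement)

        fd(v_in, g_in)
        fd(v_ctx, g_ctx)
        fd(v_negs, g_negs)

    def test_objective_increases_over_early_epochs(self):
        rng = np.random.default_rng(3)
        corpus = _two_clique_corpus(rng)
        # fixed evaluation triples: observed (center, context) pairs with
        # frozen noise draws, evaluated independently of the SGD stream
        vocab = build_vocab(corpus)
        pairs = []
        for walk in corpus.walks[:40]:
            toks = walk.tokens
            for i in range(0, len(toks) - 2, 2):
                negs = [vocab.tokens[rng.integers(len(vocab))]
                        for _ in range(5)]
                pairs.append((toks[i], toks[i + 2], negs))
        values = []
        for epochs in range(1, 6):
            emb = train_skipgram(corpus, SkipgramParams(
                embedding_size=16, context=2, epochs=epochs,
                subsample_t=1.0, seed=11))
            values.append(mean_pair_objective(emb, pairs))
        assert all(b > a for a, b in zip(values, values[1:]))

    @pytest.mark.parametrize("seed", range(5))
    def test_two_cliques_separate(self, seed):
        rng = np.random.default_rng(100 + seed)
        corpus = _two_clique_corpus(rng)
        emb = train_skipgram(corpus, SkipgramParams(
            embedding_size=16, context=2, epochs=10, subsample_t=1.0,
            seed=seed))
        a = [f"a{i}" for i in range(1, 6)]
        b = [f"b{i}" for i in range(1, 6)]
        intra = np.mean([cosine_similarity(emb[x], emb[y])
                         for g in (a, b)
                         for x, y in itertools.combinations(g, 2)])
        inter = np.mean([cosine_similarity(emb[x], emb[y])
                         for x in a for y in b])
        assert intra > inter


class TestTraining:
    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(5)
        corpus = _two_clique_corpus(rng, n_walks=40)
        p = SkipgramParams(embedding_size=8, context=2, epochs=3, seed=4)
        e1 = train_skipgram(corpus, p)
        e2 = train_skipgram(corpus, p)
        assert np.array_equal(e1.vectors, e2.vectors)

    def test_degenerate_vocabulary_rejected(self):
        corpus = _corpus(["a"])
        with pytest.raises(DegenerateVocabularyError):
            train_skipgram(corpus, SkipgramParams(negatives=5))

    def test_every_walked_token_has_a_vector(self):
        rng = np.random.default_rng(6)
        corpus = _two_clique_corpus(rng, n_walks=20)
        emb = train_skipgram(corpus, SkipgramParams(embedding_size=8,
                                                    context=2, epochs=1))
        for walk in corpus.walks:
            for tok in walk.tokens:
                assert tok in emb

    def test_word2vec_text_roundtrip(self):
        rng = np.random.default_rng(8)
        corpus = _two_clique_corpus(rng, n_walks=20)
        emb = train_skipgram(corpus, SkipgramParams(embedding_size=8,
                                                    context=2, epochs=1))
        buf = io.StringIO()
        emb.write_word2vec(buf)
        buf.seek(0)
        back = EmbeddingSet.read_word2vec(buf)
        assert back.vocab.tokens == emb.vocab.tokens
        assert np.allclose(back.vectors, emb.vectors)


class TestSimilarity:
    @pytest.mark.parametrize("v1,v2,expected", [
        ((1, 0), (1, 0), 1.0),
        ((1, 0), (0, 1), 0.0),
        ((1, 0), (1, 1), 1 / np.sqrt(2)),
    ])
    def test_closed_forms(self, v1, v2, expected):
        assert cosine_similarity(np.array(v1), np.array(v2)) \
            == pytest.approx(expected)

    def test_scale_invariance(self):
        rng = np.random.default_rng(1)
        v = rng.normal(size=12)
        for alpha in (0.01, 3.0, 1e4):
            assert cosine_similarity(v, alpha * v) == pytest.approx(1.0)

    def test_zero_vector_undefined(self):
        with pytest.raises(UndefinedSimilarityError):
            cosine_similarity(np.zeros(3), np.ones(3))

    def test_nearest_neighbors_against_brute_force(self):
        rng = np.random.default_rng(2)
        corpus = _two_clique_corpus(rng, n_walks=30)
        emb = train_skipgram(corpus, SkipgramParams(embedding_size=8,
                                                    context=2, epochs=2))
        query = "a1"
        brute = sorted(
            ((t, cosine_similarity(emb[query], emb[t]))
             for t in emb.vocab.tokens if t != query),
            key=lambda p: (-p[1], p[0]))
        got = nearest_neighbors(emb, query, top_n=len(emb.vocab))
        assert [t for t, _ in got] == [t for t, _ in brute]
        assert len(nearest_neighbors(emb, query, top_n=3)) == 3
        # top_n beyond the vocabulary returns the full list, no error
        assert len(nearest_neighbors(emb, query, top_n=10_000)) \
            == len(emb.vocab) - 1
        with pytest.raises(EntityNotFoundError):
            nearest_neighbors(emb, "nope", 3)
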