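"""Skip-gram embeddings with negative sampling over walk corpora.

The model maximizes the average log probability of context tokens within a
window c around each center token, with the log-probability replaced by the
negative-sampling discriminator

    log σ(v'_O · v_I) + Σ_{i=1..k} E_{w_i ~ Pn(w)} [log σ(-v'_{w_i} · v_I)]

where v are input vectors (the embeddings), v' output vectors, and Pn the
noise distribution (unigram frequency raised to the 3/4 power).  Frequent
tokens — in walk corpora, dominated by the small set of edge labels — are
discarded during training with probability max(0, 1 - sqrt(t/f)).

Training is plain sequential SGD (numba-compiled) with a linearly decaying
learning rate; it is deterministic for a fixed (corpus, params, seed).
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, TextIO, Tuple

import numpy as np

from ._sgns import train_epochs
from .errors import (DegenerateVocabularyError, EntityNotFoundError,
                     InvalidArgumentError, UndefinedSimilarityError)
from .walks import WalkCorpus


@dataclass
class Vocabulary:
    """Token inventory with corpus-relative frequencies (min count 1)."""

    tokens: List[str]
    index: Dict[str, int]
    counts: np.ndarray
    total: int

    def frequency(self, token: str) -> float:
        return float(self.counts[self.index[token]]) / self.total

    def __len__(self) -> int:
        return len(self.tokens)

    def __contains__(self, token: str) -> bool:
        return token in self.index


@dataclass
class SkipgramParams:
    """Hyper-parameters; defaults are the tuned full-scale values."""

    embedding_size: int = 512
    context: int = 10
    negatives: int = 5
    subsample_t: float = 1e-3
    epochs: int = 5
    alpha: float = 0.025
    min_alpha: float = 1e-4
    seed: int = 0

    def validate(self) -> None:
        if self.embedding_size < 1 or self.context < 1 or self.negatives < 0:
            raise InvalidArgumentError("invalid skip-gram dimensions")
        if not 0.0 < self.subsample_t <= 1.0:
            raise InvalidArgumentError("subsample threshold must be in (0, 1]")
        if self.epochs < 1:
            raise InvalidArgumentError("epochs must be >= 1")


class EmbeddingSet:
    """token -> input vector map; output vectors kept for training math."""

    def __init__(self, vocab: Vocabulary, vectors: np.ndarray,
                 out_vectors: Optional[np.ndarray] = None):
        self.vocab = vocab
        self.vectors = vectors
        self._out = out_vectors

    def __contains__(self, token: str) -> bool:
        return token in self.vocab

    def __getitem__(self, token: str) -> np.ndarray:
        try:
            return self.vectors[self.vocab.index[token]]
        except KeyError:
            raise EntityNotFoundError(f"no embedding for token {token!r}")

    def get(self, token: str) -> Optional[np.ndarray]:
        i = self.vocab.index.get(token)
        return None if i is None else self.vectors[i]

    @property
    def dimension(self) -> int:
        return self.vectors.shape[1]

    # ------------------------------------------------------------------ I/O
    def write_word2vec(self, sink: TextIO) -> None:
        """Standard word2vec text format: header, then one token per line."""
        sink.write(f"{len(self.vocab)} {self.dimension}\n")
        for i, tok in enumerate(self.vocab.tokens):
            comps = " ".join(repr(float(x)) for x in self.vectors[i])
            sink.write(f"{tok} {comps}\n")

    @classmethod
    def read_word2vec(cls, source: TextIO) -> "EmbeddingSet":
        header = source.readline().split()
        n, dim = int(header[0]), int(header[1])
        tokens, rows = [], np.empty((n, dim))
        for i in range(n):
            parts = source.readline().rstrip("\n").split(" ")
            tokens.append(parts[0])
            rows[i] = [float(x) for x in parts[1:dim + 1]]
        vocab = Vocabulary(tokens, {t: i for i, t in enumerate(tokens)},
                           np.ones(n, dtype=np.int64), n)
        return cls(vocab, rows)


# ---------------------------------------------------------------------------
def build_vocab(corpus: WalkCorpus) -> Vocabulary:
    """Exact token counts over the corpus; every token is kept."""
    counts: Dict[str, int] = {}
    total = 0
    for walk in corpus.walks:
        for tok in walk.tokens:
            counts[tok] = counts.get(tok, 0) + 1
            total += 1
    if total == 0:
        raise InvalidArgumentError("empty corpus")
    tokens = sorted(counts)
    return Vocabulary(tokens=tokens,
                      index={t: i for i, t in enumerate(tokens)},
                      counts=np.array([counts[t] for t in tokens], dtype=np.int64),
                      total=total)


def subsample_discard_prob(f: float, t: float) -> float:
    """Probability of discarding a token of relative frequency f.

    The frequent-word subsampling rule max(0, 1 - sqrt(t/f)): tokens at or
    below the threshold are never discarded.
    """
    if f <= 0.0 or t <= 0.0:
        raise InvalidArgumentError("frequency and threshold must be positive")
    return max(0.0, 1.0 - math.sqrt(t / f))


def _noise_cdf(counts: np.ndarray) -> np.ndarray:
    pow_counts = counts.astype(np.float64) ** 0.75
    cdf = np.cumsum(pow_counts)
    cdf /= cdf[-1]
    cdf[-1] = 1.0
    return cdf


def train_skipgram(corpus: WalkCorpus, params: SkipgramParams) -> EmbeddingSet:
    """Train skip-gram embeddings on the walk corpus.

    Single-worker sequential SGD; deterministic under ``params.seed``.
    Raises :class:`DegenerateVocabularyError` when negative sampling has no
    token to draw besides the center.
    """
    params.validate()
    vocab = build_vocab(corpus)
    if len(vocab) < 2 and params.negatives > 0:
        raise DegenerateVocabularyError(
            "negative sampling needs at least two vocabulary tokens")
    sentences = corpus.sentences()
    flat = np.fromiter(
        (vocab.index[tok] for sent in sentences for tok in sent),
        dtype=np.int32, count=vocab.total)
    offsets = np.zeros(len(sentences) + 1, dtype=np.int64)
    pos = 0
    for i, sent in enumerate(sentences):
        pos += len(sent)
        offsets[i + 1] = pos

    freqs = vocab.counts / vocab.total
    keep = np.minimum(1.0, np.sqrt(params.subsample_t / freqs))
    cum = _noise_cdf(vocab.counts)

    rng = np.random.default_rng(params.seed)
    win_in = (rng.random((len(vocab), params.embedding_size)) - 0.5) \
        / params.embedding_size
    win_out = np.zeros((len(vocab), params.embedding_size))
    train_epochs(flat, offsets, win_in, win_out, keep, cum,
                 params.context, params.negatives, params.alpha,
                 params.min_alpha, params.epochs, params.seed % (2 ** 31))
    return EmbeddingSet(vocab, win_in, win_out)


# ---------------------------------------------------------------------------
# The negative-sampling term and its analytic gradient (used for checking
# the kernel against finite differences, and as an independent evaluator of
# training progress).
# ---------------------------------------------------------------------------
def _log_sigmoid(x: np.ndarray) -> np.ndarray:
    return -np.logaddexp(0.0, -x)


def sgns_objective(v_in: np.ndarray, v_ctx: np.ndarray,
                   v_negs: np.ndarray) -> float:
    """log σ(v_ctx·v_in) + Σ_i log σ(-v_negs[i]·v_in)."""
    pos = float(_log_sigmoid(v_ctx @ v_in))
    neg = float(np.sum(_log_sigmoid(-(v_negs @ v_in)))) if len(v_negs) else 0.0
    return pos + neg


def sgns_gradients(v_in: np.ndarray, v_ctx: np.ndarray, v_negs: np.ndarray
                   ) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Analytic gradients of :func:`sgns_objective` w.r.t. each argument."""
    sig_pos = 1.0 / (1.0 + np.exp(-(v_ctx @ v_in)))
    g_in = (1.0 - sig_pos) * v_ctx
    g_ctx = (1.0 - sig_pos) * v_in
    if len(v_negs):
        sig_neg = 1.0 / (1.0 + np.exp(-(v_negs @ v_in)))
        g_in = g_in - sig_neg @ v_negs
        g_negs = -np.outer(sig_neg, v_in)
    else:
        g_negs = np.zeros_like(v_negs)
    return g_in, g_ctx, g_negs


def mean_pair_objective(emb: EmbeddingSet,
                        triples: Sequence[Tuple[str, str, Sequence[str]]]
                        ) -> float:
    """Mean negative-sampling term over fixed (center, context, noise) triples.

    Uses the trained input and output vectors; the evaluation set is fixed
    by the caller, making this a training-progress probe independent of the
    SGD stream.
    """
    if emb._out is None:
        raise InvalidArgumentError("embedding set has no output vectors")
    vals = []
    for center, ctx, negs in triples:
        v_in = emb.vectors[emb.vocab.index[center]]
        v_ctx = emb._out[emb.vocab.index[ctx]]
        v_negs = emb._out[[emb.vocab.index[n] for n in negs]]
        vals.append(sgns_objective(v_in, v_ctx, v_negs))
    return float(np.mean(vals))


# ---------------------------------------------------------------------------
# Similarity queries
# ---------------------------------------------------------------------------
def cosine_similarity(v1: np.ndarray, v2: np.ndarray) -> float:
    """dot(v1, v2) / (||v1|| ||v2||); undefined for zero vectors."""
    v1 = np.asarray(v1, dtype=np.float64)
    v2 = np.asarray(v2, dtype=np.float64)
    if v1.shape != v2.shape:
        raise InvalidArgumentError("dimension mismatch")
    n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
    if n1 == 0.0 or n2 == 0.0:
        raise UndefinedSimilarityError("cosine similarity of a zero vector")
    return float(np.dot(v1, v2) / (n1 * n2))


def nearest_neighbors(emb: EmbeddingSet, token: str,
                      top_n: int = 10) -> List[Tuple[str, float]]:
    """Tokens ranked by descending cosine similarity to ``token``.

    The query itself is excluded; ties break lexicographically; a ``top_n``
    beyond the vocabulary simply returns everything.
    """
    if token not in emb.vocab:
        raise EntityNotFoundError(f"unknown token {token!r}")
    q = emb[token]
    qn = np.linalg.norm(q)
    if qn == 0.0:
        raise UndefinedSimilarityError("query embedding is a zero vector")
    norms = np.linalg.norm(emb.vectors, axis=1)
    safe = np.where(norms == 0.0, 1.0, norms)
    sims = (emb.vectors @ q) / (safe * qn)
    sims[norms == 0.0] = -np.inf
    scored = [(tok, float(sims[i])) for i, tok in enumerate(emb.vocab.tokens)
              if tok != token]
    scored.sort(key=lambda p: (-p[1], p[0]))
    return scored[:max(0, top_n)] if top_n < len(scored) else scored
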