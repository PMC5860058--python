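"""Edge-labeled random walks over a knowledge graph.

A walk of length n from v0 is a token sequence (v0, l1, v1, ..., ln, vn):
at every step a uniformly random *outgoing* edge of the current node is
followed, contributing its label and its target.  Instantiation and
subclass edges of the (closed) graph are traversed exactly like relational
edges, under the reserved ``rdf:type`` / ``rdfs:subClassOf`` label tokens.
A walk that reaches a node without outgoing edges truncates early.

Corpus generation draws ``walks_per_node`` walks from every start node,
each start node using an independent RNG substream derived from the corpus
seed, so the output is identical regardless of scheduling.
"""
from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, TextIO, Tuple, Union

import numpy as np

from .errors import (CorpusFormatError, EntityNotFoundError,
                     InvalidArgumentError)
from .kg_core import KnowledgeGraph


@dataclass(frozen=True)
class Walk:
    """Alternating node/label token sequence; nodes at even positions."""

    tokens: Tuple[str, ...]

    def __len__(self) -> int:
        return len(self.tokens)

    @property
    def nodes(self) -> Tuple[str, ...]:
        return self.tokens[0::2]

    @property
    def labels(self) -> Tuple[str, ...]:
        return self.tokens[1::2]


@dataclass
class WalkCorpus:
    walks: List[Walk]
    walk_length: int
    walks_per_node: int
    start_set: Tuple[str, ...]
    seed: int

    def sentences(self) -> List[List[str]]:
        return [list(w.tokens) for w in self.walks]


INVERSE_SUFFIX = "_inv"


class GraphView:
    """Immutable adjacency view with deterministically ordered out-edges.

    With ``include_reverse`` every edge is additionally traversable
    backwards under a synthesized inverse label (``prop_inv``); default off
    — walks follow the directed semantics of the relations.
    """

    def __init__(self, kg: KnowledgeGraph, include_reverse: bool = False):
        adj: Dict[str, List[Tuple[str, str]]] = {}
        for t in kg.edges:
            adj.setdefault(t.subject, []).append((t.property, t.object))
            if include_reverse:
                adj.setdefault(t.object, []).append(
                    (t.property + INVERSE_SUFFIX, t.subject))
        for k in adj:
            adj[k].sort()
        self._adj = adj
        self._nodes = kg.nodes()

    def out_edges(self, node: str) -> Sequence[Tuple[str, str]]:
        return self._adj.get(node, ())

    def __contains__(self, node: str) -> bool:
        return node in self._nodes

    def nodes(self) -> List[str]:
        return sorted(self._nodes)


def random_walk(graph_view: GraphView, start: str, length: int,
                rng: np.random.Generator) -> Walk:
    """One uniform edge-labeled random walk of at most ``length`` edges."""
    if start not in graph_view:
        raise EntityNotFoundError(f"start node {start!r} not in graph")
    if length < 1:
        raise InvalidArgumentError("walk length must be >= 1")
    tokens = [start]
    current = start
    for _ in range(length):
        outs = graph_view.out_edges(current)
        if not outs:
            break
        label, target = outs[int(rng.integers(len(outs)))]
        tokens.append(label)
        tokens.append(target)
        current = target
    return Walk(tuple(tokens))


def generate_corpus(kg: Union[KnowledgeGraph, GraphView], walks_per_node: int,
                    length: int, start_set: Optional[Iterable[str]] = None,
                    seed: int = 0, include_reverse: bool = False) -> WalkCorpus:
    """Draw ``walks_per_node`` walks from every node of the start set.

    ``start_set`` defaults to all graph nodes.  Each start node owns an
    independent RNG substream spawned from ``seed``, so corpora are
    bit-identical for identical (graph, parameters, seed).
    """
    view = kg if isinstance(kg, GraphView) \
        else GraphView(kg, include_reverse=include_reverse)
    if walks_per_node < 1:
        raise InvalidArgumentError("walks_per_node must be >= 1")
    starts = sorted(set(start_set)) if start_set is not None else view.nodes()
    if not starts:
        raise InvalidArgumentError("empty start set")
    for node in starts:
        if node not in view:
            raise EntityNotFoundError(f"start node {node!r} not in graph")
    walks: List[Walk] = []
    for i, node in enumerate(starts):
        rng = np.random.default_rng(np.random.SeedSequence([seed, i]))
        for _ in range(walks_per_node):
            walks.append(random_walk(view, node, length, rng))
    return WalkCorpus(walks=walks, walk_length=length,
                      walks_per_node=walks_per_node,
                      start_set=tuple(starts), seed=seed)


# ---------------------------------------------------------------------------
# Corpus I/O: one walk per line, single-space separated tokens.
# ---------------------------------------------------------------------------
def write_corpus(corpus: WalkCorpus, sink: TextIO) -> None:
    for walk in corpus.walks:
        for tok in walk.tokens:
            if any(ch.isspace() for ch in tok):
                raise CorpusFormatError(f"token contains whitespace: {tok!r}")
        sink.write(" ".join(walk.tokens))
        sink.write("\n")


def corpus_to_text(corpus: WalkCorpus) -> str:
    buf = io.StringIO()
    write_corpus(corpus, buf)
    return buf.getvalue()


def read_corpus(source: TextIO, walk_length: int = 0, walks_per_node: int = 0,
                seed: int = 0) -> WalkCorpus:
    """Inverse of :func:`write_corpus`; validates token alternation."""
    walks: List[Walk] = []
    starts: List[str] = []
    for lineno, line in enumerate(source, start=1):
        line = line.rstrip("\n")
        if not line:
            continue
        tokens = line.split(" ")
        if len(tokens) % 2 == 0:
            raise CorpusFormatError(
                f"line {lineno}: even token count {len(tokens)} violates "
                "node/label alternation")
        walks.append(Walk(tuple(tokens)))
        starts.append(tokens[0])
    return WalkCorpus(walks=walks, walk_length=walk_length,
                      walks_per_node=walks_per_node,
                      start_set=tuple(sorted(set(starts))), seed=seed)
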