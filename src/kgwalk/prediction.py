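"""Per-relation edge prediction with type-constrained negatives.

The protocol mirrors the remove-and-rebuild cross-validation design: for
each fold, one fifth of the edges of the property under study is held out,
the *training* graph (without them) is deductively closed, walked and
embedded, and a logistic-regression model is fit on concatenated endpoint
embeddings of the retained positives plus an equal number of sampled
negatives.  Negatives are node pairs whose endpoint categories match the
relation's source/target categories and which are non-edges of the
*original* graph.  Held-out positives that re-appear in the training
closure (re-derived by inference from surviving edges) are deleted from
the training graph and counted as potential leakage.
"""
from __future__ import annotations

import itertools
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import f1_score, roc_auc_score

from .embeddings import EmbeddingSet, SkipgramParams, train_skipgram
from .errors import (EntityNotFoundError, InfeasibleNegativesError,
                     InvalidArgumentError, MissingEmbeddingError,
                     UndefinedMetricError)
from .kg_core import KnowledgeGraph, Triple, partition_edges
from .reasoner import materialize
from .walks import generate_corpus

log = logging.getLogger(__name__)

Pair = Tuple[str, str]


@dataclass
class EvalParams:
    """Stage parameters for one cross-validation run."""

    walks_per_node: int = 100
    walk_length: int = 20
    skipgram: SkipgramParams = field(default_factory=SkipgramParams)
    reasoning: bool = True
    feature_mode: str = "concat"  # or "hadamard"
    folds: int = 5

    def record(self) -> Dict:
        d = asdict(self)
        return d


@dataclass
class FoldMetrics:
    fold: int
    f_measure: float
    rocauc: float
    leakage: int
    seed: int
    n_test_pos: int


@dataclass
class EvalReport:
    """Per-fold and mean metrics plus full provenance."""

    property: str
    folds: List[FoldMetrics]
    mean_f: float
    mean_auc: float
    leakage: int
    seed: int
    params: Dict

    def to_json(self) -> str:
        d = {"property": self.property,
             "folds": [asdict(f) for f in self.folds],
             "mean_f_measure": self.mean_f,
             "mean_rocauc": self.mean_auc,
             "leakage": self.leakage,
             "seed": self.seed,
             "params": self.params}
        return json.dumps(d, indent=2, sort_keys=True)

    def to_tsv(self) -> str:
        lines = ["fold\tf_measure\trocauc\tleakage\tn_test_pos\tseed"]
        for f in self.folds:
            lines.append(f"{f.fold}\t{f.f_measure:.6f}\t{f.rocauc:.6f}"
                         f"\t{f.leakage}\t{f.n_test_pos}\t{f.seed}")
        return "\n".join(lines) + "\n"


class EdgeModel:
    """Binary logistic-regression scorer for one property's edges."""

    def __init__(self, clf: LogisticRegression, prop: str, emb: EmbeddingSet,
                 feature_mode: str):
        self._clf = clf
        self.property = prop
        self._emb = emb
        self.feature_mode = feature_mode

    def score_pairs(self, pairs: Sequence[Pair]) -> np.ndarray:
        X = _pair_features(pairs, self._emb, self.feature_mode)
        return self._clf.predict_proba(X)[:, 1]


# ---------------------------------------------------------------------------
def property_endpoint_categories(kg: KnowledgeGraph, prop: str
                                 ) -> Tuple[str, str]:
    """The (source, target) category of a property's edges; must be unique."""
    edges = kg.edges_with_property(prop)
    if not edges:
        raise EntityNotFoundError(f"no edges with property {prop!r}")
    src = {kg.categories.get(t.subject) for t in edges}
    tgt = {kg.categories.get(t.object) for t in edges}
    if len(src) != 1 or len(tgt) != 1 or None in src or None in tgt:
        raise InvalidArgumentError(
            f"{prop!r} endpoint categories are not well defined: "
            f"sources {src}, targets {tgt}")
    return src.pop(), tgt.pop()


def sample_negatives(kg: KnowledgeGraph, prop: str, n: int, seed: int,
                     exclude: Iterable[Pair] = ()) -> List[Pair]:
    """n type-constrained non-edges of the *original* graph.

    Sources share the property's source category, targets its target
    category; pairs that are ``prop`` edges of ``kg`` or listed in
    ``exclude`` are never drawn.  Deterministic under ``seed``.
    """
    src_cat, tgt_cat = property_endpoint_categories(kg, prop)
    sources = sorted(x for x in kg.individuals
                     if kg.categories.get(x) == src_cat)
    targets = sorted(x for x in kg.individuals
                     if kg.categories.get(x) == tgt_cat)
    forbidden: Set[Pair] = {(t.subject, t.object)
                            for t in kg.edges_with_property(prop)}
    forbidden |= set(exclude)
    candidates = [(u, v) for u in sources for v in targets
                  if u != v and (u, v) not in forbidden]
    if len(candidates) < n:
        raise InfeasibleNegativesError(
            f"only {len(candidates)} candidate negatives for {prop!r}, "
            f"need {n}", available=len(candidates))
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(candidates), size=n, replace=False)
    return [candidates[i] for i in sorted(idx)]


def _pair_features(pairs: Sequence[Pair], emb: EmbeddingSet,
                   mode: str = "concat") -> np.ndarray:
    missing = sorted({tok for pair in pairs for tok in pair if tok not in emb})
    if missing:
        raise MissingEmbeddingError(
            f"endpoints without embeddings: {missing[:10]}"
            + ("..." if len(missing) > 10 else ""))
    if mode == "concat":
        return np.array([np.concatenate([emb[u], emb[v]]) for u, v in pairs])
    if mode == "hadamard":
        return np.array([emb[u] * emb[v] for u, v in pairs])
    raise InvalidArgumentError(f"unknown feature mode {mode!r}")


def train_edge_model(positives: Sequence[Pair], negatives: Sequence[Pair],
                     emb: EmbeddingSet, prop: str = "",
                     feature_mode: str = "concat") -> EdgeModel:
    """Fit the penalized logistic model on concatenated endpoint embeddings."""
    if not positives or not negatives:
        raise InvalidArgumentError("both classes must be non-empty")
    X = _pair_features(list(positives) + list(negatives), emb, feature_mode)
    y = np.r_[np.ones(len(positives)), np.zeros(len(negatives))]
    clf = LogisticRegression(C=1.0, solver="lbfgs", max_iter=2000)
    clf.fit(X, y)
    return EdgeModel(clf, prop, emb, feature_mode)


def evaluate_predictions(scores: Sequence[float], labels: Sequence[int]
                         ) -> Tuple[float, float]:
    """(F-measure at the 0.5 probability cutoff, ROCAUC).

    ROCAUC is the probability that a random positive outscores a random
    negative, ties counting one half.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if len(scores) != len(labels):
        raise InvalidArgumentError("scores and labels differ in length")
    if len(set(labels.tolist())) < 2:
        raise UndefinedMetricError("both classes are required")
    f = float(f1_score(labels, (scores >= 0.5).astype(int), zero_division=0.0))
    auc = float(roc_auc_score(labels, scores))
    return f, auc


# ---------------------------------------------------------------------------
def crossvalidate_property(kg: KnowledgeGraph, prop: str,
                           params: Optional[EvalParams] = None,
                           seed: int = 0,
                           corpus_cache: Optional[Dict] = None) -> EvalReport:
    """Remove-and-rebuild k-fold cross-validation for one property.

    The property's edges are split into ``params.folds`` disjoint chunks;
    each chunk in turn is held out, the training graph is (optionally)
    materialized — held-out triples re-derived by inference are deleted and
    counted as leakage — then walked, embedded, and scored.  Test negatives
    are resampled per fold, disjoint from the training negatives.
    """
    params = params or EvalParams()
    chunks = partition_edges(kg, prop, params.folds, seed)
    all_edges = set(kg.edges_with_property(prop))
    fold_metrics: List[FoldMetrics] = []
    for i, test_edges in enumerate(chunks):
        t0 = time.perf_counter()
        fold_seed = (seed * 1000 + i * 7 + 1) % (2 ** 31)
        train_kg = kg.copy()
        train_kg.edges.difference_update(test_edges)

        leakage = 0
        if params.reasoning:
            closed, _ = materialize(train_kg)
            rederived = [t for t in test_edges if t in closed.edges]
            leakage = len(rederived)
            closed.edges.difference_update(rederived)
            graph = closed
        else:
            graph = train_kg
        corpus = None
        key = None
        if corpus_cache is not None:
            key = (prop, i, seed, params.walks_per_node, params.walk_length,
                   params.reasoning)
            corpus = corpus_cache.get(key)
        if corpus is None:
            corpus = generate_corpus(graph, params.walks_per_node,
                                     params.walk_length, seed=fold_seed)
            if key is not None:
                corpus_cache[key] = corpus
        sg = SkipgramParams(**{**asdict(params.skipgram), "seed": fold_seed})
        emb = train_skipgram(corpus, sg)

        train_pos = [(t.subject, t.object)
                     for t in sorted(all_edges - set(test_edges))]
        test_pos = [(t.subject, t.object) for t in test_edges]
        train_neg = sample_negatives(kg, prop, len(train_pos), fold_seed)
        test_neg = sample_negatives(kg, prop, len(test_pos), fold_seed + 1,
                                    exclude=train_neg)
        model = train_edge_model(train_pos, train_neg, emb, prop,
                                 params.feature_mode)
        scores = model.score_pairs(test_pos + test_neg)
        labels = [1] * len(test_pos) + [0] * len(test_neg)
        f, auc = evaluate_predictions(scores, labels)
        fold_metrics.append(FoldMetrics(fold=i, f_measure=f, rocauc=auc,
                                        leakage=leakage, seed=fold_seed,
                                        n_test_pos=len(test_pos)))
        log.info("fold %d/%d of %s: F=%.3f AUC=%.3f leakage=%d (%.1fs)",
                 i + 1, params.folds, prop, f, auc, leakage,
                 time.perf_counter() - t0)
    return EvalReport(
        property=prop, folds=fold_metrics,
        mean_f=float(np.mean([m.f_measure for m in fold_metrics])),
        mean_auc=float(np.mean([m.rocauc for m in fold_metrics])),
        leakage=sum(m.leakage for m in fold_metrics),
        seed=seed, params=params.record())


# ---------------------------------------------------------------------------
def shared_relation_pairs(kg: KnowledgeGraph, entities: Sequence[str],
                          via_props: Sequence[str]) -> Set[Pair]:
    """Unordered entity pairs sharing >= 1 target of any listed property."""
    targets: Dict[str, Set[Tuple[str, str]]] = {e: set() for e in entities}
    entity_set = set(entities)
    for p in via_props:
        for t in kg.edges_with_property(p):
            if t.subject in entity_set:
                targets[t.subject].add((p, t.object))
    out: Set[Pair] = set()
    ents = sorted(entity_set)
    for a, b in itertools.combinations(ents, 2):
        if targets[a] & targets[b]:
            out.add((a, b))
    return out


def pair_shared_relation_task(kg: KnowledgeGraph, entities: Sequence[str],
                              via_props: Sequence[str], emb: EmbeddingSet,
                              train_fraction: float = 0.8,
                              seed: int = 0) -> EvalReport:
    """Predict whether two entities share a target of the given relation(s).

    ``emb`` must be trained on a graph from which the ``via_props`` edges
    were removed (the caller owns that removal).  Pairs sharing at least one
    target in the *original* graph are positives; an equal number of
    non-sharing pairs are negatives; the stated train fraction of pairs is
    used for fitting and the rest for the reported ROCAUC.
    """
    if len(set(entities)) < 2:
        raise InvalidArgumentError("need at least two entities")
    if not 0.0 < train_fraction < 1.0:
        raise InvalidArgumentError("train_fraction must be in (0,1)")
    positives = sorted(shared_relation_pairs(kg, entities, via_props))
    ents = sorted(set(entities))
    all_pairs = [(a, b) for a, b in itertools.combinations(ents, 2)]
    negatives_pool = [p for p in all_pairs if p not in set(positives)]
    if not positives or not negatives_pool:
        raise InvalidArgumentError("pair task needs both classes")
    rng = np.random.default_rng(seed)
    n = min(len(positives), len(negatives_pool))
    pos_idx = rng.choice(len(positives), size=n, replace=False)
    neg_idx = rng.choice(len(negatives_pool), size=n, replace=False)
    pos = [positives[i] for i in sorted(pos_idx)]
    neg = [negatives_pool[i] for i in sorted(neg_idx)]

    def split(items: List[Pair]) -> Tuple[List[Pair], List[Pair]]:
        order = rng.permutation(len(items))
        cut = int(round(train_fraction * len(items)))
        return ([items[i] for i in order[:cut]],
                [items[i] for i in order[cut:]])

    train_pos, test_pos = split(pos)
    train_neg, test_neg = split(neg)
    if not (train_pos and test_pos and train_neg and test_neg):
        raise InvalidArgumentError("split left an empty class")
    model = train_edge_model(train_pos, train_neg, emb,
                             prop="+".join(via_props))
    scores = model.score_pairs(test_pos + test_neg)
    labels = [1] * len(test_pos) + [0] * len(test_neg)
    f, auc = evaluate_predictions(scores, labels)
    metrics = FoldMetrics(fold=0, f_measure=f, rocauc=auc, leakage=0,
                          seed=seed, n_test_pos=len(test_pos))
    return EvalReport(property="+".join(via_props), folds=[metrics],
                      mean_f=f, mean_auc=auc, leakage=0, seed=seed,
                      params={"train_fraction": train_fraction})


# ---------------------------------------------------------------------------
def grid_search(kg: KnowledgeGraph, prop: str, grid: Dict[str, Sequence],
                seed: int = 0,
                base_params: Optional[EvalParams] = None):
    """Rank parameter combinations by cross-validated mean AUC.

    ``grid`` maps parameter names (``embedding_size``, ``context``,
    ``walks_per_node``, ``walk_length``) to candidate values.  Walk corpora
    are cached across combinations that differ only in embedding-stage
    parameters.  Returns a pandas DataFrame sorted by descending mean AUC;
    per-cell failures are recorded, not fatal.
    """
    import pandas as pd

    base = base_params or EvalParams()
    names = sorted(grid)
    cache: Dict = {}
    rows = []
    for combo in itertools.product(*(grid[n] for n in names)):
        setting = dict(zip(names, combo))
        params = EvalParams(
            walks_per_node=setting.get("walks_per_node", base.walks_per_node),
            walk_length=setting.get("walk_length", base.walk_length),
            skipgram=SkipgramParams(**{
                **asdict(base.skipgram),
                "embedding_size": setting.get("embedding_size",
                                              base.skipgram.embedding_size),
                "context": setting.get("context", base.skipgram.context)}),
            reasoning=base.reasoning, feature_mode=base.feature_mode,
            folds=base.folds)
        row = dict(setting)
        try:
            report = crossvalidate_property(kg, prop, params, seed=seed,
                                            corpus_cache=cache)
            row["mean_auc"] = report.mean_auc
            row["mean_f_measure"] = report.mean_f
            row["error"] = ""
        except Exception as exc:  # recorded per cell
            row["mean_auc"] = float("nan")
            row["mean_f_measure"] = float("nan")
            row["error"] = str(exc)
        rows.append(row)
    frame = pd.DataFrame(rows)
    return frame.sort_values("mean_auc", ascending=False,
                             kind="mergesort").reset_index(drop=True)
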