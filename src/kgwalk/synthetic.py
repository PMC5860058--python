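"""Synthetic two-layer knowledge graphs with planted, tunable signal.

The generator emulates the structure of an integrated biomedical knowledge
graph — entity categories (drug / protein / disease), per-category class
hierarchies, reified ontology annotations, and relational edges — with a
latent-group block structure driving both the relational edges and the
annotation classes, so that every pipeline stage can be exercised and its
signal recovery measured without downloading any real database.

Planted-signal geometry.  Relational edges are drawn with within-group
probability ``p_in`` (optionally per group) and cross-group probability
``p_out``.  The default configuration uses one *dense* group and one
near-empty background group rather than two symmetric dense blocks: the
downstream edge predictor is a linear model over concatenated node
embeddings, and membership of a single dense block is linearly decodable
(an AND of two half-spaces) while symmetric "same group" parity is not.
Annotations reinforce the signal: each group owns a disjoint pool of leaf
classes from which its members are annotated.

``generate_reasoning_benefit`` builds the fixture for the with/without
reasoning contrast: interacting pairs are annotated with *distinct sibling*
leaf classes, so the token they share (the siblings' parent, and the signal
subtree ancestor) appears only in the materialized closure.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, NamedTuple, Optional, Set, Tuple, Union

import numpy as np

from . import axioms as ax
from .errors import InvalidArgumentError
from .kg_core import RDF_TYPE, KnowledgeGraph, Triple, add_annotation

_ANNOTATION_PROPS = {
    "drug": "hasSideEffect",
    "protein": "hasFunction",
    "disease": "hasPhenotype",
}


class RelationSpec(NamedTuple):
    """One planted relation: endpoint categories and block densities."""

    source: str
    target: str
    p_in: Union[float, Tuple[float, ...]]
    p_out: float


@dataclass
class SyntheticSpec:
    """Generator configuration; defaults are the reference study conditions."""

    entities: Dict[str, int] = field(default_factory=lambda: {
        "drug": 60, "protein": 80, "disease": 40})
    hierarchy_depth: int = 3
    branching: int = 3
    groups: int = 2
    relations: Dict[str, RelationSpec] = field(default_factory=lambda: {
        "hasTarget": RelationSpec("drug", "protein", (0.85, 0.02), 0.02),
        "hasIndication": RelationSpec("drug", "disease", (0.45, 0.05), 0.02),
    })
    annotation_rate: int = 2
    reified: bool = True
    noise_rate: float = 0.02
    seed: int = 0
    # reasoning-benefit fixture sizes
    signal_pairs: int = 60
    background: int = 180

    def validate(self) -> None:
        if self.hierarchy_depth < 1 or self.branching < 1:
            raise InvalidArgumentError("depth and branching must be >= 1")
        if self.groups < 1:
            raise InvalidArgumentError("need at least one latent group")
        if any(n < self.groups for n in self.entities.values()):
            raise InvalidArgumentError("more groups than entities in a category")
        for prop, r in self.relations.items():
            p_ins = r.p_in if isinstance(r.p_in, tuple) else (r.p_in,)
            if isinstance(r.p_in, tuple) and len(r.p_in) < self.groups:
                raise InvalidArgumentError(
                    f"{prop}: per-group p_in needs one value per group")
            if not all(0.0 <= r.p_out <= p <= 1.0 for p in p_ins):
                raise InvalidArgumentError(
                    f"{prop}: need 0 <= p_out <= p_in <= 1")
        if self.annotation_rate < 0 or self.noise_rate < 0:
            raise InvalidArgumentError("rates must be non-negative")


@dataclass
class GroundTruth:
    """What was planted: groups, pre-noise edges, signal classes, categories."""

    groups: Dict[str, int]
    edges: Dict[str, Set[Tuple[str, str]]]
    relation_classes: Dict[str, Dict[int, List[str]]]
    category_map: Dict[str, str]


def _build_tree(kg: KnowledgeGraph, root: str, depth: int, branching: int,
                category: str) -> List[str]:
    """Rooted class tree (subclass axioms child ⊑ parent); returns leaves."""
    kg.add_class(root, category=category)
    level = [root]
    for d in range(depth):
        nxt = []
        for parent in level:
            for b in range(branching):
                child = f"{parent}.{b}"
                kg.add_class(child, category=category)
                kg.tbox.add(ax.SubClassOf(child, parent))
                nxt.append(child)
        level = nxt
    return level


def _category_root(cat: str) -> str:
    return cat.capitalize()


def generate(spec: SyntheticSpec) -> Tuple[KnowledgeGraph, GroundTruth]:
    """Build a two-layer graph with planted group structure.

    Deterministic under ``spec.seed``.  Each entity is typed to its category
    root class, assigned a latent group, annotated (reified by default) with
    leaf classes from its group's pool, and relational edges are drawn from
    the block model of each relation, plus a ``noise_rate`` fraction of
    uniformly random extra edges.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    kg = KnowledgeGraph()
    truth = GroundTruth(groups={}, edges={}, relation_classes={},
                        category_map={})

    leaf_pools: Dict[str, List[List[str]]] = {}
    members: Dict[str, List[str]] = {}
    for cat in sorted(spec.entities):
        root = _category_root(cat)
        kg.add_class(root, category=cat)
        truth.category_map[root] = cat
        tree_root = f"{cat}A"
        leaves = _build_tree(kg, tree_root, spec.hierarchy_depth,
                             spec.branching, f"{cat}_annotation")
        truth.category_map[tree_root] = f"{cat}_annotation"
        if len(leaves) < spec.groups:
            raise InvalidArgumentError(
                f"class tree for {cat!r} has fewer leaves than groups")
        pools = [[str(x) for x in p]
                 for p in np.array_split(np.array(leaves), spec.groups)]
        leaf_pools[cat] = pools

        n = spec.entities[cat]
        names = [f"{cat}{i}" for i in range(n)]
        members[cat] = names
        group_of = rng.integers(0, spec.groups, size=n)
        # guarantee every group is inhabited
        for g in range(spec.groups):
            group_of[g % n] = g
        ann_prop = _ANNOTATION_PROPS.get(cat, f"has_{cat}_annotation")
        kg.add_property(ann_prop)
        for i, name in enumerate(names):
            g = int(group_of[i])
            kg.add_individual(name, category=cat)
            kg.add_edge(name, RDF_TYPE, root)
            truth.groups[name] = g
            pool = pools[g]
            n_ann = min(spec.annotation_rate, len(pool))
            chosen = rng.choice(len(pool), size=n_ann, replace=False)
            for c in sorted(int(j) for j in chosen):
                cls = pool[c]
                if spec.reified:
                    add_annotation(kg, name, ann_prop, cls)
                else:
                    kg.add_edge(name, ann_prop, cls)

    for prop, r in sorted(spec.relations.items()):
        kg.add_property(prop)
        srcs, tgts = members[r.source], members[r.target]
        planted: Set[Tuple[str, str]] = set()
        for u in srcs:
            gu = truth.groups[u]
            for v in tgts:
                if u == v:
                    continue
                if truth.groups[v] == gu:
                    p = r.p_in[gu] if isinstance(r.p_in, tuple) else r.p_in
                else:
                    p = r.p_out
                if rng.random() < p:
                    planted.add((u, v))
        for (u, v) in sorted(planted):
            kg.add_edge(u, prop, v)
        truth.edges[prop] = planted
        truth.relation_classes[prop] = {
            g: leaf_pools[r.source][g % len(leaf_pools[r.source])]
            for g in range(spec.groups)}
        n_noise = int(round(spec.noise_rate * len(planted)))
        added = 0
        while added < n_noise:
            u = srcs[int(rng.integers(len(srcs)))]
            v = tgts[int(rng.integers(len(tgts)))]
            if u != v and Triple(u, prop, v) not in kg.edges:
                kg.add_edge(u, prop, v)
                added += 1
    return kg, truth


def generate_reasoning_benefit(spec: SyntheticSpec
                               ) -> Tuple[KnowledgeGraph, GroundTruth]:
    """Fixture in which the predictive signal exists only after closure.

    ``spec.signal_pairs`` entity pairs interact; the two members of pair i
    are annotated with two *distinct sibling* leaf classes under a shared
    parent, and all pair parents descend from one signal-subtree ancestor.
    In the raw graph the members share no walkable token (asserted subclass
    axioms live in the TBox, not the edge set); after materialization both
    members acquire type edges to the shared parent and ancestor.
    ``spec.background`` entities carry annotations from a disjoint subtree.
    """
    spec.validate()
    if spec.hierarchy_depth < 2:
        raise InvalidArgumentError(
            "reasoning-benefit fixture needs a class tree of depth >= 2")
    rng = np.random.default_rng(spec.seed)
    kg = KnowledgeGraph()
    cat = "protein"
    root_cls = _category_root(cat)
    kg.add_class(root_cls, category=cat)
    truth = GroundTruth(groups={}, edges={}, relation_classes={},
                        category_map={root_cls: cat})

    tree_root, sig_anc, bg_anc = "fnA", "fnA.sig", "fnA.bg"
    for c in (tree_root, sig_anc, bg_anc):
        kg.add_class(c, category="function")
    kg.tbox.add(ax.SubClassOf(sig_anc, tree_root))
    kg.tbox.add(ax.SubClassOf(bg_anc, tree_root))
    truth.category_map[tree_root] = "function"

    pair_classes: Dict[int, List[str]] = {}
    for i in range(spec.signal_pairs):
        parent = f"{sig_anc}.p{i}"
        kg.add_class(parent, category="function")
        kg.tbox.add(ax.SubClassOf(parent, sig_anc))
        leaves = [f"{parent}.{j}" for j in range(2)]
        for leaf in leaves:
            kg.add_class(leaf, category="function")
            kg.tbox.add(ax.SubClassOf(leaf, parent))
        pair_classes[i] = leaves
    n_bg_leaves = max(8, spec.branching ** 2)
    bg_leaves = [f"{bg_anc}.{j}" for j in range(n_bg_leaves)]
    for leaf in bg_leaves:
        kg.add_class(leaf, category="function")
        kg.tbox.add(ax.SubClassOf(leaf, bg_anc))

    prop = "interacts"
    ann_prop = _ANNOTATION_PROPS[cat]
    kg.add_property(prop)
    kg.add_property(ann_prop)
    planted: Set[Tuple[str, str]] = set()
    for i in range(spec.signal_pairs):
        u, v = f"sp{i}a", f"sp{i}b"
        for name, leaf in ((u, pair_classes[i][0]), (v, pair_classes[i][1])):
            kg.add_individual(name, category=cat)
            kg.add_edge(name, RDF_TYPE, root_cls)
            truth.groups[name] = 1
            add_annotation(kg, name, ann_prop, leaf)
        kg.add_edge(u, prop, v)
        planted.add((u, v))
    bg_names = [f"bg{j}" for j in range(spec.background)]
    for name in bg_names:
        kg.add_individual(name, category=cat)
        kg.add_edge(name, RDF_TYPE, root_cls)
        truth.groups[name] = 0
        leaf = bg_leaves[int(rng.integers(len(bg_leaves)))]
        add_annotation(kg, name, ann_prop, leaf)
    # a few background interactions so the relation is not a pure matching
    n_noise = max(2, int(round(0.15 * spec.signal_pairs)))
    added = 0
    while added < n_noise:
        u = bg_names[int(rng.integers(len(bg_names)))]
        v = bg_names[int(rng.integers(len(bg_names)))]
        if u != v and Triple(u, prop, v) not in kg.edges:
            kg.add_edge(u, prop, v)
            added += 1
    truth.edges[prop] = planted
    truth.relation_classes[prop] = pair_classes
    return kg, truth


def scaled_down_eval_params(reasoning: bool = True,
                            feature_mode: str = "concat"):
    """Reference pipeline parameters for the synthetic fixtures.

    A desk-scale counterpart of the full-size configuration: embedding
    dimension 64, 20 walks of length 10 per node, context 5; the smaller
    corpus takes more passes (15 epochs at initial rate 0.05) to converge
    than a million-walk corpus does with the full-scale defaults.
    """
    from .embeddings import SkipgramParams
    from .prediction import EvalParams
    return EvalParams(
        walks_per_node=20, walk_length=10,
        skipgram=SkipgramParams(embedding_size=64, context=5, epochs=15,
                                alpha=0.05),
        reasoning=reasoning, feature_mode=feature_mode, folds=5)


def reasoning_benefit_eval_params(reasoning: bool = True):
    """Reference parameters for the reasoning-benefit fixture.

    Identical to :func:`scaled_down_eval_params` except that pair features
    are the Hadamard product of the endpoint embeddings: the planted signal
    is *pair-level similarity* (a shared inferred parent class), which a
    linear model can read off a multiplicative feature map but not off a
    concatenation.
    """
    return scaled_down_eval_params(reasoning=reasoning,
                                   feature_mode="hadamard")


def destroy_signal(kg: KnowledgeGraph, prop: str, seed: int) -> KnowledgeGraph:
    """Null control: replace the ``prop`` edges with uniformly random pairs.

    Endpoints are re-drawn uniformly from the categories of the original
    sources and targets (same edge count, no duplicates), which removes the
    planted block structure *and* the degree profile — the point of the
    null is that no signal of any kind survives.
    """
    edges = kg.edges_with_property(prop)
    if not edges:
        raise InvalidArgumentError(f"no edges with property {prop!r}")
    src_cats = {kg.categories.get(t.subject) for t in edges}
    tgt_cats = {kg.categories.get(t.object) for t in edges}
    srcs = sorted(n for n in kg.individuals if kg.categories.get(n) in src_cats)
    tgts = sorted(n for n in kg.individuals if kg.categories.get(n) in tgt_cats)
    rng = np.random.default_rng(seed)
    out = kg.copy()
    out.edges.difference_update(edges)
    added: Set[Tuple[str, str]] = set()
    while len(added) < len(edges):
        u = srcs[int(rng.integers(len(srcs)))]
        v = tgts[int(rng.integers(len(tgts)))]
        if u != v and (u, v) not in added:
            added.add((u, v))
            out.add_edge(u, prop, v)
    return out
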