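"""Two-layer knowledge-graph data model and RDF I/O.

The graph has an instance layer (named individuals linked by object
properties) and a class layer (ontology classes).  The two layers are
connected by instantiation (rdf:type) edges.  Class and property axioms live
in separate boxes (``tbox``/``rbox``); asserted ``rdfs:subClassOf`` triples
are routed into the TBox on parsing, so the raw walkable edge set contains
only relational and instantiation edges.  Materialization (see
:mod:`kgwalk.reasoner`) adds entailed type and subclass edges back into the
edge set of the closed graph.

Ontology annotations follow the reified pattern: the fact that protein
*foxp2* has function GO:0003700 is stored as two edges through a freshly
minted individual, ``hasFunction(foxp2, f1)`` and ``instanceOf(f1,
GO:0003700)``.

Identifiers are plain strings.  Anything containing ``://`` is treated as an
absolute IRI; a ``prefix:local`` form is expanded through a small prefix
table; bare names are expanded under a reserved base namespace.  Round
trips through N-Triples therefore preserve identifiers exactly.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, NamedTuple, Optional, Set, Tuple

import numpy as np
import rdflib
from rdflib import BNode, Literal, URIRef
from rdflib.collection import Collection
from rdflib.namespace import OWL, RDF, RDFS

from . import axioms as ax
from .errors import (EntityNotFoundError, InvalidArgumentError, ParseError,
                     ValidationError)

log = logging.getLogger(__name__)

# Reserved edge labels for the instantiation and subclass relations.
RDF_TYPE = "rdf:type"
RDFS_SUBCLASS = "rdfs:subClassOf"

BASE = "http://kgwalk.example.org/r/"
ANN_NS = "ann:"
ANN_BASE = "http://kgwalk.example.org/ann/"
NORM_NS = "norm:"  # fresh classes minted by axiom normalization

_PREFIXES = {
    "rdf:": str(RDF),
    "rdfs:": str(RDFS),
    "owl:": str(OWL),
    "ann:": ANN_BASE,
    "GO:": "http://purl.obolibrary.org/obo/GO_",
    "HP:": "http://purl.obolibrary.org/obo/HP_",
    "DOID:": "http://purl.obolibrary.org/obo/DOID_",
}


def expand_term(ident: str) -> URIRef:
    """Map an internal identifier to a full IRI."""
    if "://" in ident:
        return URIRef(ident)
    for prefix, ns in _PREFIXES.items():
        if ident.startswith(prefix):
            return URIRef(ns + ident[len(prefix):])
    return URIRef(BASE + ident)


def contract_term(uri: URIRef) -> str:
    """Inverse of :func:`expand_term`."""
    s = str(uri)
    if s.startswith(BASE):
        return s[len(BASE):]
    for prefix, ns in _PREFIXES.items():
        if s.startswith(ns):
            return prefix + s[len(ns):]
    return s


class Triple(NamedTuple):
    """A directed labeled edge (subject, property, object)."""

    subject: str
    property: str
    object: str


class RemovalRecord(NamedTuple):
    """Provenance of a seeded random edge removal."""

    property: str
    removed: Tuple[Triple, ...]
    fraction: float
    seed: int


@dataclass(eq=True)
class KnowledgeGraph:
    """Two-layer directed labeled multigraph plus axiom boxes."""

    individuals: Set[str] = field(default_factory=set)
    classes: Set[str] = field(default_factory=set)
    properties: Set[str] = field(default_factory=set)
    edges: Set[Triple] = field(default_factory=set)
    tbox: Set[ax.ClassAxiom] = field(default_factory=set)
    rbox: Set[ax.PropertyAxiom] = field(default_factory=set)
    categories: Dict[str, str] = field(default_factory=dict)
    _ann_counter: int = field(default=0, compare=False, repr=False)

    # ------------------------------------------------------------- mutation
    def add_individual(self, name: str, category: Optional[str] = None) -> None:
        self.individuals.add(name)
        if category is not None:
            self.categories[name] = category

    def add_class(self, name: str, category: Optional[str] = None) -> None:
        self.classes.add(name)
        if category is not None:
            self.categories[name] = category

    def add_property(self, name: str) -> None:
        self.properties.add(name)

    def add_edge(self, subject: str, prop: str, obj: str) -> None:
        """Add a triple; layers must already declare the referenced names."""
        t = Triple(subject, prop, obj)
        if prop == RDF_TYPE:
            if subject not in self.individuals or obj not in self.classes:
                raise ValidationError(
                    f"instantiation edge must point individual -> class: {t}")
        elif prop == RDFS_SUBCLASS:
            if subject not in self.classes or obj not in self.classes:
                raise ValidationError(
                    f"subclass edge must point class -> class: {t}")
        else:
            if prop not in self.properties:
                raise ValidationError(f"undeclared property in {t}")
            if subject not in self.individuals and subject not in self.classes:
                raise ValidationError(f"undeclared subject in {t}")
            if obj not in self.individuals and obj not in self.classes:
                raise ValidationError(f"undeclared object in {t}")
        self.edges.add(t)

    # --------------------------------------------------------------- queries
    def nodes(self) -> Set[str]:
        return self.individuals | self.classes

    def edges_with_property(self, prop: str) -> List[Triple]:
        return sorted(t for t in self.edges if t.property == prop)

    def relational_edges(self) -> List[Triple]:
        return sorted(t for t in self.edges
                      if t.property not in (RDF_TYPE, RDFS_SUBCLASS))

    def instantiation_edges(self) -> List[Triple]:
        return sorted(t for t in self.edges if t.property == RDF_TYPE)

    def subclass_edges(self) -> List[Triple]:
        return sorted(t for t in self.edges if t.property == RDFS_SUBCLASS)

    def types_of(self, individual: str) -> Set[str]:
        return {t.object for t in self.edges
                if t.property == RDF_TYPE and t.subject == individual}

    def copy(self) -> "KnowledgeGraph":
        kg = KnowledgeGraph(
            individuals=set(self.individuals),
            classes=set(self.classes),
            properties=set(self.properties),
            edges=set(self.edges),
            tbox=set(self.tbox),
            rbox=set(self.rbox),
            categories=dict(self.categories),
        )
        kg._ann_counter = self._ann_counter
        return kg

    def validate(self) -> None:
        """Check the structural invariants, raising on violation."""
        for t in self.edges:
            if not (t.subject and t.property and t.object):
                raise ValidationError(f"empty component in {t}")
            if t.property == RDF_TYPE:
                if t.subject not in self.individuals or t.object not in self.classes:
                    raise ValidationError(f"bad instantiation edge {t}")
            elif t.property == RDFS_SUBCLASS:
                if t.subject not in self.classes or t.object not in self.classes:
                    raise ValidationError(f"bad subclass edge {t}")
            else:
                if t.property not in self.properties:
                    raise ValidationError(f"undeclared property in {t}")
                if t.subject not in self.nodes() or t.object not in self.nodes():
                    raise ValidationError(f"undeclared endpoint in {t}")

    # ------------------------------------------------------ class hierarchy
    def named_superclasses(self, cls: str) -> Set[str]:
        """Ancestors of ``cls`` through asserted named subclass axioms."""
        up: Dict[str, Set[str]] = {}
        for a in self.tbox:
            if isinstance(a, ax.SubClassOf) and isinstance(a.sub, str) \
                    and isinstance(a.sup, str):
                up.setdefault(a.sub, set()).add(a.sup)
        seen: Set[str] = set()
        stack = [cls]
        while stack:
            c = stack.pop()
            for p in up.get(c, ()):
                if p not in seen:
                    seen.add(p)
                    stack.append(p)
        return seen

    def resolve_category(self, cls: str,
                         category_map: Optional[Dict[str, str]] = None) -> Optional[str]:
        """Category tag of a class, via the map or the nearest mapped ancestor."""
        cmap = category_map if category_map is not None else self.categories
        if cls in cmap:
            return cmap[cls]
        for anc in sorted(self.named_superclasses(cls)):
            if anc in cmap:
                return cmap[anc]
        return None


# ---------------------------------------------------------------------------
# Reified annotations
# ---------------------------------------------------------------------------
def add_annotation(kg: KnowledgeGraph, entity: str, prop: str,
                   cls: str) -> Tuple[KnowledgeGraph, str]:
    """Attach an ontology-class annotation to an entity via a fresh instance.

    Mints an individual ``f`` in the reserved annotation namespace with a
    deterministic counter suffix (an IRI that occurs nowhere else in the
    graph), then adds ``prop(entity, f)`` and ``instanceOf(f, cls)``.  The
    fresh individual's category is derived from the class's category.

    Returns the (mutated) graph and the minted identifier.
    """
    if entity not in kg.individuals:
        raise EntityNotFoundError(f"unknown individual: {entity}")
    if cls not in kg.classes:
        raise EntityNotFoundError(f"unknown class: {cls}")
    kg.properties.add(prop)
    taken = kg.nodes() | kg.properties
    while True:
        kg._ann_counter += 1
        fresh = f"{ANN_NS}f{kg._ann_counter}"
        if fresh not in taken:
            break
    cat = kg.resolve_category(cls)
    kg.add_individual(fresh, category=cat)
    kg.add_edge(entity, prop, fresh)
    kg.add_edge(fresh, RDF_TYPE, cls)
    return kg, fresh


# ---------------------------------------------------------------------------
# Edge removal / partitioning (cross-validation support)
# ---------------------------------------------------------------------------
def remove_edges(kg: KnowledgeGraph, prop: str, fraction: float,
                 seed: int) -> Tuple[KnowledgeGraph, RemovalRecord]:
    """Delete ``round(fraction * n)`` uniformly sampled ``prop`` edges.

    Deterministic under ``seed``; returns a modified copy plus the record.
    """
    if not 0.0 < fraction < 1.0:
        raise InvalidArgumentError(f"fraction must be in (0,1), got {fraction}")
    candidates = kg.edges_with_property(prop)
    if not candidates:
        raise EntityNotFoundError(f"no edges with property {prop!r}")
    k = int(round(fraction * len(candidates)))
    if k < 1:
        raise InvalidArgumentError(
            f"fraction {fraction} of {len(candidates)} edges rounds to zero removals")
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(candidates), size=k, replace=False)
    removed = tuple(candidates[i] for i in sorted(idx))
    out = kg.copy()
    out.edges.difference_update(removed)
    return out, RemovalRecord(prop, removed, fraction, seed)


def partition_edges(kg: KnowledgeGraph, prop: str, folds: int,
                    seed: int) -> List[List[Triple]]:
    """Partition the ``prop`` edges into ``folds`` disjoint near-equal chunks.

    The union of the chunks is exactly the ``prop`` edge set; used by the
    cross-validation driver (each chunk plays the 20% held-out role once).
    """
    edges = kg.edges_with_property(prop)
    if len(edges) < folds:
        raise InvalidArgumentError(
            f"{prop!r} has {len(edges)} edges, fewer than {folds} folds")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(edges))
    chunks = np.array_split(order, folds)
    return [[edges[i] for i in sorted(chunk)] for chunk in chunks]


# ---------------------------------------------------------------------------
# RDF parsing
# ---------------------------------------------------------------------------
_META_PREDICATES = {RDFS.subClassOf, RDFS.subPropertyOf, OWL.equivalentClass,
                    OWL.equivalentProperty, OWL.disjointWith,
                    OWL.propertyChainAxiom, OWL.onProperty, OWL.someValuesFrom,
                    OWL.intersectionOf, RDF.first, RDF.rest}
_DECL_CLASSES = {OWL.Class, OWL.NamedIndividual, OWL.ObjectProperty,
                 OWL.TransitiveProperty, OWL.ReflexiveProperty, OWL.Restriction,
                 RDF.List}

_FORMATS = {"ntriples": "nt", "nt": "nt", "turtle": "turtle", "ttl": "turtle"}


def _parse_expr(g: rdflib.Graph, node) -> ax.ClassExpr:
    if isinstance(node, URIRef):
        return contract_term(node)
    if isinstance(node, BNode):
        inter = g.value(node, OWL.intersectionOf)
        if inter is not None:
            members = list(Collection(g, inter))
            return ax.And(tuple(_parse_expr(g, m) for m in members))
        filler = g.value(node, OWL.someValuesFrom)
        prop = g.value(node, OWL.onProperty)
        if filler is not None and prop is not None:
            return ax.Some(contract_term(prop), _parse_expr(g, filler))
    raise ValidationError(f"unsupported class expression at {node!r}")


def parse_graph(document: str, format: str = "ntriples",
                category_map: Optional[Dict[str, str]] = None,
                strict: bool = False) -> KnowledgeGraph:
    """Parse an RDF document into a :class:`KnowledgeGraph`.

    Relational and rdf:type triples become edges; subclass/subproperty/OWL
    axiom triples are routed into the TBox/RBox.  Entity categories are
    assigned from ``category_map`` (class identifier -> category tag),
    resolving through named subclass ancestors.  In strict mode a relational
    triple whose predicate is never declared an object property raises; by
    default it is declared on the fly with a logged warning.
    """
    g = rdflib.Graph()
    fmt = _FORMATS.get(format)
    if fmt is None:
        raise InvalidArgumentError(f"unknown format {format!r}")
    try:
        g.parse(data=document, format=fmt)
    except Exception as exc:  # rdflib raises several parser error types
        raise ParseError(f"malformed {format} document: {exc}") from exc

    kg = KnowledgeGraph()
    declared_props: Set[str] = set()

    # Pass 1: declarations.
    for s, p, o in g.triples((None, RDF.type, None)):
        if o == OWL.Class and isinstance(s, URIRef):
            kg.classes.add(contract_term(s))
        elif o == OWL.NamedIndividual and isinstance(s, URIRef):
            kg.individuals.add(contract_term(s))
        elif o in (OWL.ObjectProperty, OWL.TransitiveProperty,
                   OWL.ReflexiveProperty) and isinstance(s, URIRef):
            name = contract_term(s)
            kg.properties.add(name)
            declared_props.add(name)
            if o == OWL.TransitiveProperty:
                kg.rbox.add(ax.Transitive(name))
            elif o == OWL.ReflexiveProperty:
                kg.rbox.add(ax.Reflexive(name))

    # Pass 2: axioms and edges.
    for s, p, o in g:
        if p == RDF.type:
            if o in _DECL_CLASSES or isinstance(s, BNode) or isinstance(o, BNode):
                continue
            subj, obj = contract_term(s), contract_term(o)
            kg.individuals.add(subj)
            kg.classes.add(obj)
            kg.edges.add(Triple(subj, RDF_TYPE, obj))
        elif p == RDFS.subClassOf:
            if isinstance(s, BNode):
                continue  # visited through its parent expression
            sub = _parse_expr(g, s)
            sup = _parse_expr(g, o)
            for e in (sub, sup):
                if isinstance(e, str):
                    kg.classes.add(e)
            kg.tbox.add(ax.SubClassOf(sub, sup))
        elif p == OWL.equivalentClass:
            kg.tbox.add(ax.EquivalentClasses(_parse_expr(g, s), _parse_expr(g, o)))
            for t in (s, o):
                if isinstance(t, URIRef):
                    kg.classes.add(contract_term(t))
        elif p == OWL.disjointWith:
            kg.tbox.add(ax.DisjointClasses(_parse_expr(g, s), _parse_expr(g, o)))
            for t in (s, o):
                if isinstance(t, URIRef):
                    kg.classes.add(contract_term(t))
        elif p == RDFS.subPropertyOf:
            a, b = contract_term(s), contract_term(o)
            kg.properties.update((a, b))
            kg.rbox.add(ax.SubPropertyOf(a, b))
        elif p == OWL.equivalentProperty:
            a, b = contract_term(s), contract_term(o)
            kg.properties.update((a, b))
            kg.rbox.add(ax.EquivalentProperties(a, b))
        elif p == OWL.propertyChainAxiom:
            links = [contract_term(m) for m in Collection(g, o)]
            if len(links) != 2:
                raise ValidationError(
                    f"only binary property chains are supported, got {links}")
            sup = contract_term(s)
            kg.properties.update(links + [sup])
            kg.rbox.add(ax.Chain(links[0], links[1], sup))
        elif p in _META_PREDICATES or isinstance(s, BNode) or isinstance(o, BNode):
            continue
        elif isinstance(o, Literal):
            continue  # data values carry no graph structure here
        else:
            prop = contract_term(p)
            subj, obj = contract_term(s), contract_term(o)
            if prop not in declared_props and prop not in kg.properties:
                if strict:
                    raise ValidationError(
                        f"undeclared property {prop!r} in strict mode")
                log.warning("declaring undeclared property %r on the fly", prop)
            kg.properties.add(prop)
            for n in (subj, obj):
                if n not in kg.classes:
                    kg.individuals.add(n)
            kg.edges.add(Triple(subj, prop, obj))

    # Declare names mentioned only inside axiom expressions.
    for a in kg.tbox:
        for part in a:
            cls_names, prop_names = _expr_names(part)
            kg.classes.update(cls_names)
            kg.properties.update(prop_names)

    # Categories from the config map, resolved through the hierarchy.
    if category_map:
        for cls in sorted(kg.classes):
            cat = kg.resolve_category(cls, category_map)
            if cat is not None:
                kg.categories[cls] = cat
        for t in kg.instantiation_edges():
            cat = kg.categories.get(t.object)
            if cat is not None and t.subject not in kg.categories:
                kg.categories[t.subject] = cat
    kg._ann_counter = _max_ann_counter(kg)
    return kg


def _expr_names(expr: ax.ClassExpr) -> Tuple[Set[str], Set[str]]:
    """Named classes and properties mentioned in a class expression."""
    if isinstance(expr, str):
        return {expr}, set()
    if isinstance(expr, ax.And):
        cs: Set[str] = set()
        ps: Set[str] = set()
        for op in expr.operands:
            c, p = _expr_names(op)
            cs |= c
            ps |= p
        return cs, ps
    if isinstance(expr, ax.Some):
        cs, ps = _expr_names(expr.filler)
        return cs, ps | {expr.prop}
    raise ValidationError(f"unsupported class expression {expr!r}")


def _max_ann_counter(kg: KnowledgeGraph) -> int:
    best = 0
    for name in kg.individuals:
        if name.startswith(ANN_NS + "f"):
            suffix = name[len(ANN_NS) + 1:]
            if suffix.isdigit():
                best = max(best, int(suffix))
    return best


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------
def _expr_node(g: rdflib.Graph, expr: ax.ClassExpr, counter: List[int]):
    if isinstance(expr, str):
        return expand_term(expr)
    counter[0] += 1
    node = BNode(f"x{counter[0]}")
    if isinstance(expr, ax.And):
        members = [_expr_node(g, m, counter) for m in expr.operands]
        lst = BNode(f"x{counter[0]}l")
        Collection(g, lst, members)
        g.add((node, OWL.intersectionOf, lst))
        g.add((node, RDF.type, OWL.Class))
    elif isinstance(expr, ax.Some):
        g.add((node, RDF.type, OWL.Restriction))
        g.add((node, OWL.onProperty, expand_term(expr.prop)))
        g.add((node, OWL.someValuesFrom, _expr_node(g, expr.filler, counter)))
    else:
        raise ValidationError(f"cannot serialize expression {expr!r}")
    return node


def serialize_graph(kg: KnowledgeGraph, format: str = "ntriples") -> str:
    """Serialize to N-Triples, one triple per line, lexicographically sorted.

    Declarations for every individual/class/property are emitted so parsing
    reconstructs the layers; TBox/RBox axioms use their standard OWL/RDFS
    encodings.  Subclass *edges* of a closed graph collapse onto the same
    rdfs:subClassOf triples as the corresponding TBox axioms.
    """
    if _FORMATS.get(format) != "nt":
        raise InvalidArgumentError("only ntriples serialization is supported")
    g = rdflib.Graph()
    counter = [0]
    # Declarations are emitted only where the layer of a name cannot be
    # inferred from the triples themselves (keeps documents minimal and the
    # round trip exact).
    inf_ind: Set[str] = set()
    inf_cls: Set[str] = set()
    inf_prop: Set[str] = set()
    for t in kg.edges:
        if t.property == RDF_TYPE:
            inf_ind.add(t.subject)
            inf_cls.add(t.object)
        elif t.property == RDFS_SUBCLASS:
            inf_cls.update((t.subject, t.object))
        else:
            inf_prop.add(t.property)
    for t in kg.edges:
        if t.property not in (RDF_TYPE, RDFS_SUBCLASS):
            for n in (t.subject, t.object):
                if n not in kg.classes:
                    inf_ind.add(n)
    for a in kg.tbox:
        for part in a:
            cs, ps = _expr_names(part)
            inf_cls |= cs
            inf_prop |= ps
    for a in kg.rbox:
        if isinstance(a, ax.Chain):
            inf_prop.update((a.first, a.second, a.sup))
        elif isinstance(a, (ax.SubPropertyOf, ax.EquivalentProperties)):
            inf_prop.update((a[0], a[1]))
        else:
            inf_prop.add(a.prop)
    for name in kg.individuals - inf_ind:
        g.add((expand_term(name), RDF.type, OWL.NamedIndividual))
    for name in kg.classes - inf_cls:
        g.add((expand_term(name), RDF.type, OWL.Class))
    for name in kg.properties - inf_prop:
        g.add((expand_term(name), RDF.type, OWL.ObjectProperty))
    for t in kg.edges:
        if t.property == RDF_TYPE:
            g.add((expand_term(t.subject), RDF.type, expand_term(t.object)))
        elif t.property == RDFS_SUBCLASS:
            g.add((expand_term(t.subject), RDFS.subClassOf, expand_term(t.object)))
        else:
            g.add((expand_term(t.subject), expand_term(t.property),
                   expand_term(t.object)))
    for a in kg.tbox:
        if isinstance(a, ax.SubClassOf):
            g.add((_expr_node(g, a.sub, counter), RDFS.subClassOf,
                   _expr_node(g, a.sup, counter)))
        elif isinstance(a, ax.EquivalentClasses):
            g.add((_expr_node(g, a.a, counter), OWL.equivalentClass,
                   _expr_node(g, a.b, counter)))
        elif isinstance(a, ax.DisjointClasses):
            g.add((_expr_node(g, a.a, counter), OWL.disjointWith,
                   _expr_node(g, a.b, counter)))
    for a in kg.rbox:
        if isinstance(a, ax.SubPropertyOf):
            g.add((expand_term(a.sub), RDFS.subPropertyOf, expand_term(a.sup)))
        elif isinstance(a, ax.EquivalentProperties):
            g.add((expand_term(a.a), OWL.equivalentProperty, expand_term(a.b)))
        elif isinstance(a, ax.Transitive):
            g.add((expand_term(a.prop), RDF.type, OWL.TransitiveProperty))
        elif isinstance(a, ax.Reflexive):
            g.add((expand_term(a.prop), RDF.type, OWL.ReflexiveProperty))
        elif isinstance(a, ax.Chain):
            lst = BNode(f"chain{counter[0]}")
            counter[0] += 1
            Collection(g, lst, [expand_term(a.first), expand_term(a.second)])
            g.add((expand_term(a.sup), OWL.propertyChainAxiom, lst))
    lines = sorted(f"{s.n3()} {p.n3()} {o.n3()} ." for s, p, o in g)
    return "\n".join(lines) + ("\n" if lines else "")
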