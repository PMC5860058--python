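"""Forward-chaining materialization under an EL rule subset.

The deductive closure KG⊨ of a knowledge graph extends its edge set with
every entailed fact expressible between *named* entities:

* relational edges r(x, y) entailed through subproperties, transitivity,
  property chains and reflexivity;
* instantiation edges C(x) entailed through the (saturated) class
  hierarchy, class conjunctions and existential restrictions on the left;
* subclass edges C ⊑ D between named classes from TBox saturation.

Existential restrictions on the right-hand side (A ⊑ ∃r.B) never mint
anonymous individuals — they participate only in TBox saturation, keeping
the closure inside the named-entity fragment.  Disjointness violations are
collected into the closure report rather than raised.

The engine runs semi-naive (delta-driven) rounds to a fixpoint; the test
suite checks it against an independent naive one-rule-at-a-time oracle on
random instances.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, List, Set, Tuple

from . import axioms as ax
from .errors import UnsupportedAxiomError
from .kg_core import NORM_NS, RDF_TYPE, RDFS_SUBCLASS, KnowledgeGraph, Triple


@dataclass
class ClosureReport:
    """Summary of one materialization run."""

    inferred_triples: int
    iterations: int
    disjointness_violations: List[Tuple[str, str, str]] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------
class _Normalizer:
    def __init__(self) -> None:
        self.subclass: Set[Tuple[str, str]] = set()
        self.conj: Set[Tuple[str, str, str]] = set()
        self.exist_lhs: Set[Tuple[str, str, str]] = set()
        self.exist_rhs: Set[Tuple[str, str, str]] = set()
        self.disjoint: Set[Tuple[str, str]] = set()
        self.fresh: Set[str] = set()
        self._counter = 0

    def fresh_class(self) -> str:
        self._counter += 1
        name = f"{NORM_NS}X{self._counter}"
        self.fresh.add(name)
        return name

    def name_of(self, expr: ax.ClassExpr) -> str:
        """Return a named class N with expr ⊑ N (fresh if expr is complex)."""
        if isinstance(expr, str):
            return expr
        n = self.fresh_class()
        self.add_sub(expr, n)
        return n

    def add_sub(self, sub: ax.ClassExpr, sup: ax.ClassExpr) -> None:
        # Complex right-hand sides first.
        if isinstance(sup, ax.And):
            for member in sup.operands:
                self.add_sub(sub, member)
            return
        if isinstance(sup, ax.Some):
            a = self.name_of(sub) if not isinstance(sub, str) else sub
            filler = sup.filler
            if not isinstance(filler, str):
                b = self.fresh_class()
                self.add_sub(b, filler)  # fresh name entails the filler
                filler_name = b
            else:
                filler_name = filler
            self.exist_rhs.add((a, sup.prop, filler_name))
            return
        if not isinstance(sup, str):
            raise UnsupportedAxiomError(f"unsupported class expression: {sup!r}")

        # Named right-hand side; decompose the left.
        if isinstance(sub, str):
            self.subclass.add((sub, sup))
        elif isinstance(sub, ax.And):
            ops = list(sub.operands)
            if len(ops) < 2:
                raise UnsupportedAxiomError(f"degenerate intersection {sub!r}")
            names = [self.name_of(op) for op in ops]
            # Fold an n-ary conjunction into binary ConjunctionSubclass steps.
            acc = names[0]
            for nxt in names[1:-1]:
                inter = self.fresh_class()
                self.conj.add((acc, nxt, inter))
                acc = inter
            self.conj.add((acc, names[-1], sup))
        elif isinstance(sub, ax.Some):
            filler = self.name_of(sub.filler)
            self.exist_lhs.add((sub.prop, filler, sup))
        else:
            raise UnsupportedAxiomError(f"unsupported class expression: {sub!r}")


def normalize_axioms(tbox: Iterable[ax.ClassAxiom],
                     rbox: Iterable[ax.PropertyAxiom]) -> ax.NormalizedAxiomSet:
    """Rewrite axioms into the six class and five property normal forms.

    Equivalences become subsumption pairs in both directions; nested
    intersections/existentials are flattened through fresh intermediate
    class names.  Raises :class:`UnsupportedAxiomError` for anything outside
    the supported constructors.
    """
    n = _Normalizer()
    for a in tbox:
        if isinstance(a, ax.SubClassOf):
            n.add_sub(a.sub, a.sup)
        elif isinstance(a, ax.EquivalentClasses):
            n.add_sub(a.a, a.b)
            n.add_sub(a.b, a.a)
        elif isinstance(a, ax.DisjointClasses):
            n.disjoint.add((n.name_of(a.a), n.name_of(a.b)))
        else:
            raise UnsupportedAxiomError(f"unsupported class axiom: {a!r}")
    subprop: Set[Tuple[str, str]] = set()
    transitive: Set[str] = set()
    reflexive: Set[str] = set()
    chains: Set[Tuple[str, str, str]] = set()
    for a in rbox:
        if isinstance(a, ax.SubPropertyOf):
            subprop.add((a.sub, a.sup))
        elif isinstance(a, ax.EquivalentProperties):
            subprop.add((a.a, a.b))
            subprop.add((a.b, a.a))
        elif isinstance(a, ax.Transitive):
            transitive.add(a.prop)
        elif isinstance(a, ax.Reflexive):
            reflexive.add(a.prop)
        elif isinstance(a, ax.Chain):
            chains.add((a.first, a.second, a.sup))
        else:
            raise UnsupportedAxiomError(f"unsupported property axiom: {a!r}")
    return ax.NormalizedAxiomSet(
        subclass=frozenset(n.subclass), conj=frozenset(n.conj),
        exist_lhs=frozenset(n.exist_lhs), exist_rhs=frozenset(n.exist_rhs),
        disjoint=frozenset(n.disjoint), subprop=frozenset(subprop),
        transitive=frozenset(transitive), reflexive=frozenset(reflexive),
        chains=frozenset(chains), fresh_classes=frozenset(n.fresh))


# ---------------------------------------------------------------------------
# TBox saturation
# ---------------------------------------------------------------------------
def _subprop_closure(norm: ax.NormalizedAxiomSet,
                     props: Set[str]) -> Dict[str, Set[str]]:
    """Reflexive-transitive super-property map r -> {s : r ⊑* s}."""
    up: Dict[str, Set[str]] = {p: {p} for p in props}
    for r, s in norm.subprop:
        up.setdefault(r, {r}).add(s)
        up.setdefault(s, {s})
    changed = True
    while changed:
        changed = False
        for r in up:
            new = set()
            for s in up[r]:
                new |= up.get(s, {s})
            if not new <= up[r]:
                up[r] |= new
                changed = True
    return up


def saturate_tbox(norm: ax.NormalizedAxiomSet,
                  classes: Iterable[str]) -> Set[Tuple[str, str]]:
    """Least fixpoint of the subsumption rules, restricted to named classes.

    Rules: reflexivity C ⊑ C; transitivity; conjunction firing; and the
    existential composition C ⊑ ∃r.A, A ⊑ A', ∃s.A' ⊑ B with r ⊑* s
    entailing C ⊑ B.  Fresh normalization classes participate internally
    but are removed from the returned set.
    """
    subs, _ = _saturate_internal(norm, classes)
    named = set(classes)
    return {(c, d) for (c, d) in subs
            if c in named and d in named}


def _saturate_internal(norm: ax.NormalizedAxiomSet, classes: Iterable[str]
                       ) -> Tuple[Set[Tuple[str, str]], Set[Tuple[str, str, str]]]:
    all_classes = set(classes) | norm.fresh_classes
    for (a, b) in norm.subclass:
        all_classes.update((a, b))
    for (a1, a2, b) in norm.conj:
        all_classes.update((a1, a2, b))
    for (r, a, b) in norm.exist_lhs:
        all_classes.update((a, b))
    for (a, r, b) in norm.exist_rhs:
        all_classes.update((a, b))
    props = set()
    for (r, s) in norm.subprop:
        props.update((r, s))
    for (r, a, b) in norm.exist_lhs:
        props.add(r)
    for (a, r, b) in norm.exist_rhs:
        props.add(r)
    up = _subprop_closure(norm, props)

    subs: Set[Tuple[str, str]] = {(c, c) for c in all_classes}
    subs |= set(norm.subclass)
    links: Set[Tuple[str, str, str]] = set()  # (C, r, B) meaning C ⊑ ∃r.B

    changed = True
    while changed:
        changed = False
        # transitivity
        sup_of: Dict[str, Set[str]] = {}
        for (c, d) in subs:
            sup_of.setdefault(c, set()).add(d)
        new: Set[Tuple[str, str]] = set()
        for (c, d) in subs:
            for e in sup_of.get(d, ()):
                if (c, e) not in subs:
                    new.add((c, e))
        # conjunction
        for (a1, a2, b) in norm.conj:
            for c in all_classes:
                if (c, a1) in subs and (c, a2) in subs and (c, b) not in subs:
                    new.add((c, b))
        # existential introduction: A ⊑ ∃r.B axiom lifts to any C ⊑ A
        new_links: Set[Tuple[str, str, str]] = set()
        for (a, r, b) in norm.exist_rhs:
            for c in all_classes:
                if (c, a) in subs and (c, r, b) not in links:
                    new_links.add((c, r, b))
        # existential elimination: C ⊑ ∃r.A, A ⊑ A', ∃s.A' ⊑ B, r ⊑* s
        for (c, r, a) in links:
            for (s, a2, b) in norm.exist_lhs:
                if s in up.get(r, {r}) and (a, a2) in subs and (c, b) not in subs:
                    new.add((c, b))
        if new or new_links:
            subs |= new
            links |= new_links
            changed = True
    return subs, links


# ---------------------------------------------------------------------------
# ABox materialization
# ---------------------------------------------------------------------------
def materialize(kg: KnowledgeGraph,
                reflexive_all_individuals: bool = True
                ) -> Tuple[KnowledgeGraph, ClosureReport]:
    """Compute the deductive closure KG⊨ of ``kg``.

    Adds, to fixpoint: type inheritance through the saturated class
    hierarchy; subproperty, transitivity, chain and reflexivity inferences
    on relational edges; conjunction and left-existential class inferences;
    and all saturated subsumptions as subclass edges (reflexive C ⊑ C pairs
    are kept internal, never emitted as self-loop edges).  With
    ``reflexive_all_individuals`` (default), a reflexive property r yields
    r(x, x) for every named individual x.

    Returns the closed graph and a report with the inferred-triple count,
    the number of semi-naive rounds, and any disjointness violations.
    """
    norm = normalize_axioms(kg.tbox, kg.rbox)
    subs, _ = _saturate_internal(norm, kg.classes)
    sup_of: Dict[str, Set[str]] = {}
    for (c, d) in subs:
        if c != d:
            sup_of.setdefault(c, set()).add(d)

    conj_by_left: Dict[str, List[Tuple[str, str]]] = {}
    conj_by_right: Dict[str, List[Tuple[str, str]]] = {}
    for (a1, a2, b) in norm.conj:
        conj_by_left.setdefault(a1, []).append((a2, b))
        conj_by_right.setdefault(a2, []).append((a1, b))
    exl_by_prop: Dict[str, List[Tuple[str, str]]] = {}
    for (r, a, b) in norm.exist_lhs:
        exl_by_prop.setdefault(r, []).append((a, b))
    subprop_direct: Dict[str, Set[str]] = {}
    for (r, s) in norm.subprop:
        subprop_direct.setdefault(r, set()).add(s)
    chains_by_first: Dict[str, List[Tuple[str, str]]] = {}
    chains_by_second: Dict[str, List[Tuple[str, str]]] = {}
    for (r, s, q) in norm.chains:
        chains_by_first.setdefault(r, []).append((s, q))
        chains_by_second.setdefault(s, []).append((r, q))

    # State: relational facts and type facts (types include fresh classes
    # internally; they are filtered on output).
    rel: Set[Tuple[str, str, str]] = set()
    types: Set[Tuple[str, str]] = set()
    out_by: Dict[Tuple[str, str], Set[str]] = {}   # (prop, x) -> {y}
    in_by: Dict[Tuple[str, str], Set[str]] = {}    # (prop, y) -> {x}
    types_of: Dict[str, Set[str]] = {}
    has_type: Dict[str, Set[str]] = {}             # class -> {x}

    def rel_fact(x: str, r: str, y: str) -> bool:
        if (x, r, y) in rel:
            return False
        rel.add((x, r, y))
        out_by.setdefault((r, x), set()).add(y)
        in_by.setdefault((r, y), set()).add(x)
        return True

    def type_fact(x: str, c: str) -> bool:
        if (x, c) in types:
            return False
        types.add((x, c))
        types_of.setdefault(x, set()).add(c)
        has_type.setdefault(c, set()).add(x)
        return True

    delta_rel: List[Tuple[str, str, str]] = []
    delta_type: List[Tuple[str, str]] = []
    for t in kg.edges:
        if t.property == RDF_TYPE:
            if type_fact(t.subject, t.object):
                delta_type.append((t.subject, t.object))
        elif t.property == RDFS_SUBCLASS:
            continue  # re-derived from saturation
        else:
            if rel_fact(t.subject, t.property, t.object):
                delta_rel.append((t.subject, t.property, t.object))
    if reflexive_all_individuals:
        for r in sorted(norm.reflexive):
            for x in kg.individuals:
                if rel_fact(x, r, x):
                    delta_rel.append((x, r, x))

    iterations = 0
    while delta_rel or delta_type:
        iterations += 1
        new_rel: List[Tuple[str, str, str]] = []
        new_type: List[Tuple[str, str]] = []

        for (x, r, y) in delta_rel:
            # R2 subproperty
            for s in subprop_direct.get(r, ()):
                if rel_fact(x, s, y):
                    new_rel.append((x, s, y))
            # R3 transitivity
            if r in norm.transitive:
                for z in list(out_by.get((r, y), ())):
                    if rel_fact(x, r, z):
                        new_rel.append((x, r, z))
                for w in list(in_by.get((r, x), ())):
                    if rel_fact(w, r, y):
                        new_rel.append((w, r, y))
            # R4 chains: r as first link, r as second link
            for (s, q) in chains_by_first.get(r, ()):
                for z in list(out_by.get((s, y), ())):
                    if rel_fact(x, q, z):
                        new_rel.append((x, q, z))
            for (p, q) in chains_by_second.get(r, ()):
                for w in list(in_by.get((p, x), ())):
                    if rel_fact(w, q, y):
                        new_rel.append((w, q, y))
            # R7 existential on the left
            for (a, b) in exl_by_prop.get(r, ()):
                if a in types_of.get(y, ()):
                    if type_fact(x, b):
                        new_type.append((x, b))

        for (x, c) in delta_type:
            # R1 via saturated hierarchy
            for d in sup_of.get(c, ()):
                if type_fact(x, d):
                    new_type.append((x, d))
            # R6 conjunction
            for (a2, b) in conj_by_left.get(c, ()):
                if a2 in types_of.get(x, ()):
                    if type_fact(x, b):
                        new_type.append((x, b))
            for (a1, b) in conj_by_right.get(c, ()):
                if a1 in types_of.get(x, ()):
                    if type_fact(x, b):
                        new_type.append((x, b))
            # R7 triggered by a late-arriving type on the edge target
            for r, pairs in exl_by_prop.items():
                for (a, b) in pairs:
                    if a == c:
                        for w in list(in_by.get((r, x), ())):
                            if type_fact(w, b):
                                new_type.append((w, b))

        delta_rel, delta_type = new_rel, new_type

    closed = kg.copy()
    fresh = norm.fresh_classes
    for (x, r, y) in rel:
        closed.edges.add(Triple(x, r, y))
    for (x, c) in types:
        if c not in fresh:
            closed.classes.add(c)
            closed.edges.add(Triple(x, RDF_TYPE, c))
    for (c, d) in subs:
        if c != d and c not in fresh and d not in fresh:
            closed.classes.update((c, d))
            closed.edges.add(Triple(c, RDFS_SUBCLASS, d))

    violations = _violations(norm, has_type)
    report = ClosureReport(
        inferred_triples=len(closed.edges) - len(kg.edges),
        iterations=iterations,
        disjointness_violations=violations)
    return closed, report


def _violations(norm: ax.NormalizedAxiomSet,
                has_type: Dict[str, Set[str]]) -> List[Tuple[str, str, str]]:
    out = []
    for (a, b) in sorted(norm.disjoint):
        for x in sorted(has_type.get(a, set()) & has_type.get(b, set())):
            out.append((x, a, b))
    return out


def check_consistency(kg: KnowledgeGraph) -> List[Tuple[str, str, str]]:
    """All (individual, A, B) with DisjointClasses(A, B) and both types held.

    The closure is computed internally; violations are reported, not raised.
    """
    _, report = materialize(kg)
    return report.disjointness_violations
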