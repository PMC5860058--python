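"""Independent brute-force oracles for the reasoner tests.

The naive closure oracle applies one inference rule at a time over full
cross products until nothing changes — no indexes, no deltas — and is kept
deliberately separate from the engine it checks.
"""
from __future__ import annotations

import itertools
from typing import Dict, List, Set, Tuple

import numpy as np

from kgwalk import axioms as ax
from kgwalk.kg_core import RDF_TYPE, RDFS_SUBCLASS, KnowledgeGraph, Triple
from kgwalk.reasoner import normalize_axioms


def naive_closure(kg: KnowledgeGraph, rule_rng=None) -> Set[Triple]:
    """One-rule-at-a-time fixpoint closure of a knowledge graph.

    With ``rule_rng`` the order in which rules are attempted is shuffled on
    every pass — the fixpoint must not depend on it.
    """
    norm = normalize_axioms(kg.tbox, kg.rbox)
    fresh = set(norm.fresh_classes)
    classes = set(kg.classes) | fresh
    for (a, b) in norm.subclass:
        classes.update((a, b))
    for (a1, a2, b) in norm.conj:
        classes.update((a1, a2, b))
    for (r, a, b) in norm.exist_lhs:
        classes.update((a, b))
    for (a, r, b) in norm.exist_rhs:
        classes.update((a, b))

    # reflexive-transitive super-property closure, by repeated squaring-free scan
    props = set()
    for (r, s) in norm.subprop:
        props.update((r, s))
    for (r, a, b) in norm.exist_lhs:
        props.add(r)
    for (a, r, b) in norm.exist_rhs:
        props.add(r)
    up: Dict[str, Set[str]] = {p: {p} for p in props}
    for (r, s) in norm.subprop:
        up.setdefault(r, {r}).add(s)
        up.setdefault(s, {s})
    while True:
        grown = False
        for r in up:
            for s in list(up[r]):
                for q in up.get(s, {s}):
                    if q not in up[r]:
                        up[r].add(q)
                        grown = True
        if not grown:
            break

    subs: Set[Tuple[str, str]] = {(c, c) for c in classes} | set(norm.subclass)
    links: Set[Tuple[str, str, str]] = set()
    rel: Set[Tuple[str, str, str]] = set()
    types: Set[Tuple[str, str]] = set()
    for t in kg.edges:
        if t.property == RDF_TYPE:
            types.add((t.subject, t.object))
        elif t.property != RDFS_SUBCLASS:
            rel.add((t.subject, t.property, t.object))
    for r in norm.reflexive:
        for x in kg.individuals:
            rel.add((x, r, x))

    def t_trans() -> bool:
        for (c, d), (d2, e) in itertools.product(list(subs), list(subs)):
            if d == d2 and (c, e) not in subs:
                subs.add((c, e))
                return True
        return False

    def t_conj() -> bool:
        for (a1, a2, b) in norm.conj:
            for c in classes:
                if (c, a1) in subs and (c, a2) in subs and (c, b) not in subs:
                    subs.add((c, b))
                    return True
        return False

    def t_exist_intro() -> bool:
        for (a, r, b) in norm.exist_rhs:
            for c in classes:
                if (c, a) in subs and (c, r, b) not in links:
                    links.add((c, r, b))
                    return True
        return False

    def t_exist_elim() -> bool:
        for (c, r, a) in list(links):
            for (s, a2, b) in norm.exist_lhs:
                if s in up.get(r, {r}) and (a, a2) in subs \
                        and (c, b) not in subs:
                    subs.add((c, b))
                    return True
        return False

    def a_type() -> bool:
        for (x, c) in list(types):
            for (c2, d) in subs:
                if c == c2 and (x, d) not in types:
                    types.add((x, d))
                    return True
        return False

    def a_subprop() -> bool:
        for (x, r, y) in list(rel):
            for (r2, s) in norm.subprop:
                if r == r2 and (x, s, y) not in rel:
                    rel.add((x, s, y))
                    return True
        return False

    def a_trans() -> bool:
        for (x, r, y) in list(rel):
            if r in norm.transitive:
                for (y2, r2, z) in list(rel):
                    if r2 == r and y2 == y and (x, r, z) not in rel:
                        rel.add((x, r, z))
                        return True
        return False

    def a_chain() -> bool:
        for (r, s, q) in norm.chains:
            for (x, r2, y) in list(rel):
                if r2 != r:
                    continue
                for (y2, s2, z) in list(rel):
                    if s2 == s and y2 == y and (x, q, z) not in rel:
                        rel.add((x, q, z))
                        return True
        return False

    def a_conj() -> bool:
        for (a1, a2, b) in norm.conj:
            for x in kg.individuals:
                if (x, a1) in types and (x, a2) in types \
                        and (x, b) not in types:
                    types.add((x, b))
                    return True
        return False

    def a_exl() -> bool:
        for (r, a, b) in norm.exist_lhs:
            for (x, r2, y) in list(rel):
                if r2 == r and (y, a) in types and (x, b) not in types:
                    types.add((x, b))
                    return True
        return False

    rules = [t_trans, t_conj, t_exist_intro, t_exist_elim, a_type,
             a_subprop, a_trans, a_chain, a_conj, a_exl]
    while True:
        order = list(rules)
        if rule_rng is not None:
            rule_rng.shuffle(order)
        if not any(rule() for rule in order):
            break

    out: Set[Triple] = set(kg.edges)
    for (x, r, y) in rel:
        out.add(Triple(x, r, y))
    for (x, c) in types:
        if c not in fresh:
            out.add(Triple(x, RDF_TYPE, c))
    for (c, d) in subs:
        if c != d and c not in fresh and d not in fresh:
            out.add(Triple(c, RDFS_SUBCLASS, d))
    return out


def naive_violations(kg: KnowledgeGraph) -> List[Tuple[str, str, str]]:
    """Disjointness scan over the naive closure."""
    norm = normalize_axioms(kg.tbox, kg.rbox)
    closure = naive_closure(kg)
    types: Dict[str, Set[str]] = {}
    for t in closure:
        if t.property == RDF_TYPE:
            types.setdefault(t.object, set()).add(t.subject)
    out = []
    for (a, b) in sorted(norm.disjoint):
        for x in sorted(types.get(a, set()) & types.get(b, set())):
            out.append((x, a, b))
    return out


# ---------------------------------------------------------------------------
def random_instance(rng: np.random.Generator) -> KnowledgeGraph:
    """Small random graph exercising all eleven axiom forms."""
    kg = KnowledgeGraph()
    n_cls = int(rng.integers(3, 7))
    n_prop = int(rng.integers(2, 4))
    n_ind = int(rng.integers(2, 16))
    classes = [f"C{i}" for i in range(n_cls)]
    props = [f"r{i}" for i in range(n_prop)]
    inds = [f"x{i}" for i in range(n_ind)]
    for c in classes:
        kg.add_class(c)
    for p in props:
        kg.add_property(p)
    for x in inds:
        kg.add_individual(x)

    def cls() -> str:
        return classes[int(rng.integers(n_cls))]

    def prop() -> str:
        return props[int(rng.integers(n_prop))]

    n_axioms = int(rng.integers(5, 41))
    for _ in range(n_axioms):
        kind = int(rng.integers(11))
        if kind == 0:
            kg.tbox.add(ax.SubClassOf(cls(), cls()))
        elif kind == 1:
            kg.tbox.add(ax.EquivalentClasses(cls(), cls()))
        elif kind == 2:
            kg.tbox.add(ax.DisjointClasses(cls(), cls()))
        elif kind == 3:  # conjunction on the left, occasionally nested
            left = ax.And((cls(), cls()))
            if rng.random() < 0.3:
                left = ax.And((left, cls()))
            kg.tbox.add(ax.SubClassOf(left, cls()))
        elif kind == 4:  # existential on the left
            kg.tbox.add(ax.SubClassOf(ax.Some(prop(), cls()), cls()))
        elif kind == 5:  # existential on the right
            kg.tbox.add(ax.SubClassOf(cls(), ax.Some(prop(), cls())))
        elif kind == 6:
            kg.rbox.add(ax.SubPropertyOf(prop(), prop()))
        elif kind == 7:
            kg.rbox.add(ax.EquivalentProperties(prop(), prop()))
        elif kind == 8:
            kg.rbox.add(ax.Transitive(prop()))
        elif kind == 9:
            kg.rbox.add(ax.Reflexive(prop()))
        else:
            kg.rbox.add(ax.Chain(prop(), prop(), prop()))

    n_types = int(rng.integers(1, 2 * n_ind + 1))
    for _ in range(n_types):
        kg.add_edge(inds[int(rng.integers(n_ind))], RDF_TYPE, cls())
    n_rel = int(rng.integers(1, 2 * n_ind + 1))
    for _ in range(n_rel):
        x = inds[int(rng.integers(n_ind))]
        y = inds[int(rng.integers(n_ind))]
        kg.add_edge(x, prop(), y)
    return kg


# ---------------------------------------------------------------------------
def propositional_entails(axioms, goal_sub, goal_sup, classes) -> bool:
    """Model-enumeration entailment for conjunction-only axioms.

    Interprets each axiom element-wise (no existentials): enumerates all
    truth assignments of class membership for a single domain element and
    checks that every model of ``axioms`` satisfies ``goal_sub ⊑ goal_sup``.
    """
    classes = sorted(classes)

    def holds(expr, assign) -> bool:
        if isinstance(expr, str):
            return assign[expr]
        if isinstance(expr, ax.And):
            return all(holds(op, assign) for op in expr.operands)
        raise ValueError(f"unsupported expression {expr!r}")

    for bits in itertools.product([False, True], repeat=len(classes)):
        assign = dict(zip(classes, bits))
        ok = True
        for (sub, sup) in axioms:
            if holds(sub, assign) and not holds(sup, assign):
                ok = False
                break
        if ok and holds(goal_sub, assign) and not holds(goal_sup, assign):
            return False
    return True
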