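"""EL class expressions and axioms.

A class expression is either a named class (a plain string identifier), a
conjunction :class:`And`, or an existential restriction :class:`Some`.
Axioms split into two boxes: class axioms (TBox) and object-property axioms
(RBox).  Only constructs of the EL profile that the reasoner handles are
representable here; normalization rejects anything else.

The reasoner works on :class:`NormalizedAxiomSet`, in which every class
axiom is in one of six normal forms (named subclass, conjunction subclass,
existential on either side, disjointness — equivalence having been rewritten
away) and every property axiom in one of five (subproperty, transitivity,
reflexivity, binary chain — property equivalence rewritten away).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import FrozenSet, NamedTuple, Tuple, Union

ClassExpr = Union[str, "And", "Some"]


class And(NamedTuple):
    """Class intersection A1 ⊓ A2 ⊓ ... (n-ary; flattened at normalization)."""

    operands: Tuple[ClassExpr, ...]


class Some(NamedTuple):
    """Existential restriction ∃prop.filler."""

    prop: str
    filler: ClassExpr


def intersection(*operands: ClassExpr) -> And:
    """Convenience constructor for :class:`And`."""
    if len(operands) < 2:
        raise ValueError("intersection needs at least two operands")
    return And(tuple(operands))


def some(prop: str, filler: ClassExpr) -> Some:
    return Some(prop, filler)


# ---------------------------------------------------------------- class axioms
class SubClassOf(NamedTuple):
    sub: ClassExpr
    sup: ClassExpr


class EquivalentClasses(NamedTuple):
    a: ClassExpr
    b: ClassExpr


class DisjointClasses(NamedTuple):
    a: ClassExpr
    b: ClassExpr


ClassAxiom = Union[SubClassOf, EquivalentClasses, DisjointClasses]


# ------------------------------------------------------------- property axioms
class SubPropertyOf(NamedTuple):
    sub: str
    sup: str


class EquivalentProperties(NamedTuple):
    a: str
    b: str


class Transitive(NamedTuple):
    prop: str


class Reflexive(NamedTuple):
    prop: str


class Chain(NamedTuple):
    """Property chain first ∘ second ⊑ sup (binary chains only)."""

    first: str
    second: str
    sup: str


PropertyAxiom = Union[SubPropertyOf, EquivalentProperties, Transitive, Reflexive, Chain]


@dataclass(frozen=True)
class NormalizedAxiomSet:
    """Axioms reduced to the normal forms the rule engine consumes.

    ``fresh_classes`` names the intermediate classes introduced while
    flattening nested expressions; they participate in saturation and rule
    firing but are filtered from every materialized triple.
    """

    subclass: FrozenSet[Tuple[str, str]] = frozenset()          # A ⊑ B
    conj: FrozenSet[Tuple[str, str, str]] = frozenset()          # A1 ⊓ A2 ⊑ B
    exist_lhs: FrozenSet[Tuple[str, str, str]] = frozenset()     # ∃r.A ⊑ B
    exist_rhs: FrozenSet[Tuple[str, str, str]] = frozenset()     # A ⊑ ∃r.B
    disjoint: FrozenSet[Tuple[str, str]] = frozenset()           # A ⊓ B ⊑ ⊥
    subprop: FrozenSet[Tuple[str, str]] = frozenset()            # r ⊑ s
    transitive: FrozenSet[str] = frozenset()
    reflexive: FrozenSet[str] = frozenset()
    chains: FrozenSet[Tuple[str, str, str]] = frozenset()        # r ∘ s ⊑ q
    fresh_classes: FrozenSet[str] = frozenset()

    def named_class_axiom_count(self) -> int:
        return (len(self.subclass) + len(self.conj) + len(self.exist_lhs)
                + len(self.exist_rhs) + len(self.disjoint))
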