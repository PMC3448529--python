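"""Structural subsumption reasoning over the class-expression language.

The fragment is conjunctive-existential (EL-style): conjunctions of named
classes and existential restrictions.  ``subsumes(G, S)`` decides whether a
homomorphism exists from the description tree of the general expression G into
the tree of the specific expression S, where

* an atom A in G maps onto an atom B in S whenever B is a (reflexive,
  transitive) ``is_a`` descendant of A;
* a ``part-of`` edge in G matches along any chain of ``part-of`` expression
  edges and ``is_a``/``part_of`` ontology edges, including the empty chain
  (part-of is reflexive and transitive);
* a ``has-part`` edge absorbs a trailing ``part-of`` chain (the property
  chain has-part o part-of -> has-part);
* every other relation matches exactly one same-relation edge;
* a conjunction in G requires all of its operands to be matched.

Named classes carrying equivalence definitions are unfolded (with cycle
detection) before matching.  This fragment covers every construct the phene
patterns emit; no general TBox saturation is performed.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import networkx as nx

from .eq_core import (
    And,
    Atom,
    ClassExpression,
    EqphenError,
    HAS_PART,
    PART_OF,
    Some,
)
from .obo_io import Ontology

logger = logging.getLogger(__name__)

__all__ = [
    "ReasoningError",
    "AxiomSet",
    "ConsistencyResult",
    "subsumes",
    "classify",
    "infer_hierarchy",
    "check_qualifier_consistency",
    "PROCESS_QUALITY_ROOT",
    "OBJECT_QUALITY_ROOT",
]


class ReasoningError(EqphenError):
    """Ill-formed axiom sets (definitional cycles, conflicting definitions)."""


# PATO's top-level split between qualities of processes and of physical
# objects; used by the qualifier/bearer consistency check.
PROCESS_QUALITY_ROOT = "PATO:0001236"
OBJECT_QUALITY_ROOT = "PATO:0001241"

_PROCESS_NAMESPACES = frozenset({"biological_process", "molecular_function"})
_OBJECT_NAMESPACES = frozenset({"cellular_component", "cell"})


class AxiomSet:
    """Named subsumptions, equivalence definitions and sufficient conditions.

    ``equivalences`` maps a CURIE to its defining expression (necessary and
    sufficient); ``sufficient_conditions`` maps a CURIE to a list of
    expressions each of which is subsumed by the class (the encoding used for
    union definitions).  A CURIE may not carry both.

    The named hierarchy is kept as two closures: ``is_a`` alone (atom
    subsumption) and ``is_a`` union ``part_of`` (part-of path matching).
    """

    def __init__(
        self,
        equivalences: Optional[Mapping[str, ClassExpression]] = None,
        sufficient_conditions: Optional[Mapping[str, Sequence[ClassExpression]]] = None,
        isa_edges: Iterable[tuple[str, str]] = (),
        part_of_edges: Iterable[tuple[str, str]] = (),
    ):
        self.equivalences: dict[str, ClassExpression] = dict(equivalences or {})
        self.sufficient_conditions: dict[str, list[ClassExpression]] = {
            c: list(exprs) for c, exprs in (sufficient_conditions or {}).items()
        }
        overlap = set(self.equivalences) & set(self.sufficient_conditions)
        if overlap:
            raise ReasoningError(
                "classes with both an equivalence and sufficient conditions: "
                + ", ".join(sorted(overlap))
            )
        self._isa = nx.DiGraph()
        self._isa.add_edges_from(isa_edges)
        self._ispart = nx.DiGraph()
        self._ispart.add_edges_from(isa_edges)
        self._ispart.add_edges_from(part_of_edges)
        self._isa_anc: dict[str, frozenset[str]] = {}
        self._ispart_anc: dict[str, frozenset[str]] = {}
        self._unfold_cache: dict[ClassExpression, ClassExpression] = {}

    @classmethod
    def from_ontology(
        cls,
        ontology: Ontology,
        equivalences: Optional[Mapping[str, ClassExpression]] = None,
        sufficient_conditions: Optional[Mapping[str, Sequence[ClassExpression]]] = None,
    ) -> "AxiomSet":
        isa = []
        part_of = []
        for term in ontology.terms.values():
            for parent in term.is_a:
                isa.append((term.id, parent))
            for rel, target in term.relationships:
                if rel in ("part_of", PART_OF):
                    part_of.append((term.id, target))
        return cls(equivalences, sufficient_conditions, isa, part_of)

    # -- named-class closures ------------------------------------------------

    def isa_ancestors(self, curie: str) -> frozenset[str]:
        """Reflexive-transitive is_a ancestors of a named class."""
        cached = self._isa_anc.get(curie)
        if cached is None:
            if curie in self._isa:
                cached = frozenset(nx.descendants(self._isa, curie)) | {curie}
            else:
                cached = frozenset({curie})
            self._isa_anc[curie] = cached
        return cached

    def ispart_ancestors(self, curie: str) -> frozenset[str]:
        """Classes reachable via any interleaving of is_a and part_of edges."""
        cached = self._ispart_anc.get(curie)
        if cached is None:
            if curie in self._ispart:
                cached = frozenset(nx.descendants(self._ispart, curie)) | {curie}
            else:
                cached = frozenset({curie})
            self._ispart_anc[curie] = cached
        return cached

    def atom_subsumes(self, general: str, specific: str) -> bool:
        return general in self.isa_ancestors(specific)

    # -- unfolding -----------------------------------------------------------

    def unfold(self, expr: ClassExpression) -> ClassExpression:
        """Replace atoms that carry equivalence definitions by their
        definitions, recursively; definitional cycles are a hard error."""
        cached = self._unfold_cache.get(expr)
        if cached is None:
            cached = self._unfold(expr, ())
            self._unfold_cache[expr] = cached
        return cached

    def _unfold(self, expr: ClassExpression, stack: tuple[str, ...]) -> ClassExpression:
        if isinstance(expr, Atom):
            definition = self.equivalences.get(expr.curie)
            if definition is None:
                return expr
            if expr.curie in stack:
                cycle = " -> ".join(stack + (expr.curie,))
                raise ReasoningError(f"definitional cycle: {cycle}")
            return self._unfold(definition, stack + (expr.curie,))
        if isinstance(expr, Some):
            return Some(expr.relation, self._unfold(expr.filler, stack))
        if isinstance(expr, And):
            return And(self._unfold(op, stack) for op in expr.operands)
        raise TypeError(f"not a class expression: {expr!r}")


# ---------------------------------------------------------------------------
# Description-tree form and the homomorphism search
# ---------------------------------------------------------------------------


@dataclass
class _Node:
    atoms: list[str] = field(default_factory=list)
    edges: list[tuple[str, "_Node"]] = field(default_factory=list)


def _to_node(expr: ClassExpression) -> _Node:
    node = _Node()
    _collect(expr, node)
    return node


def _collect(expr: ClassExpression, node: _Node) -> None:
    if isinstance(expr, Atom):
        node.atoms.append(expr.curie)
    elif isinstance(expr, Some):
        node.edges.append((expr.relation, _to_node(expr.filler)))
    elif isinstance(expr, And):
        for op in expr.operands:
            _collect(op, node)
    else:
        raise TypeError(f"not a class expression: {expr!r}")


def _sub(g: _Node, s: _Node, ax: AxiomSet) -> bool:
    for a in g.atoms:
        if not any(ax.atom_subsumes(a, b) for b in s.atoms):
            return False
    return all(_match_edge(r, gc, s, ax) for r, gc in g.edges)


def _match_edge(relation: str, gc: _Node, s: _Node, ax: AxiomSet) -> bool:
    # single same-relation edge
    for r2, c in s.edges:
        if r2 == relation and _sub(gc, c, ax):
            return True
    if relation == PART_OF:
        # reflexivity: the empty chain
        if _sub(gc, s, ax):
            return True
        # transitivity through expression edges
        for r2, c in s.edges:
            if r2 == PART_OF and _match_edge(PART_OF, gc, c, ax):
                return True
        # chains through the named hierarchy: an atom B part_of/is_a-reaches
        # some class entailing every atom of the (edge-free) filler
        if not gc.edges and gc.atoms:
            for b in s.atoms:
                for target in ax.ispart_ancestors(b):
                    target_anc = ax.isa_ancestors(target)
                    if all(a in target_anc for a in gc.atoms):
                        return True
    elif relation == HAS_PART:
        # property chain: has-part o part-of -> has-part
        for r2, c in s.edges:
            if r2 == HAS_PART and _match_edge(PART_OF, gc, c, ax):
                return True
    return False


def subsumes(general: ClassExpression, specific: ClassExpression, axioms: AxiomSet) -> bool:
    """True iff ``general`` structurally subsumes ``specific`` under the
    axiom set.  Total; reflexive and transitive on canonical expressions."""
    g = _to_node(axioms.unfold(general))
    s = _to_node(axioms.unfold(specific))
    return _sub(g, s, axioms)


# ---------------------------------------------------------------------------
# Classification and hierarchy inference
# ---------------------------------------------------------------------------


def _class_subsumes_expr(cls_id: str, expr: ClassExpression, axioms: AxiomSet) -> bool:
    definition = axioms.equivalences.get(cls_id)
    if definition is not None:
        return subsumes(definition, expr, axioms)
    disjuncts = axioms.sufficient_conditions.get(cls_id)
    if disjuncts:
        # expr below any disjunct is below the class
        return any(subsumes(d, expr, axioms) for d in disjuncts)
    return False


def _class_leq(child: str, parent: str, axioms: AxiomSet) -> bool:
    """child ⊑ parent among defined/named classes.

    Union (sufficient-condition) classes are treated as exhaustive: the child
    is below the parent iff every disjunct is — this is what licenses e.g.
    a phenotype-of-either-X-or-Y class sliding under a broader process class.
    """
    if parent in axioms.isa_ancestors(child):
        return True
    child_defs: list[ClassExpression]
    if child in axioms.equivalences:
        child_defs = [axioms.equivalences[child]]
    elif axioms.sufficient_conditions.get(child):
        child_defs = axioms.sufficient_conditions[child]
    else:
        return False
    return all(_class_subsumes_expr(parent, e, axioms) for e in child_defs)


def classify(
    expr: ClassExpression, axioms: AxiomSet, classes: Iterable[str]
) -> tuple[list[str], list[str]]:
    """Return (all subsumers, most specific subsumers) of ``expr`` among the
    given defined classes, each sorted by CURIE.  A class is most specific if
    no other subsumer lies strictly below it."""
    pool = sorted(set(classes))
    all_subsumers = [c for c in pool if _class_subsumes_expr(c, expr, axioms)]
    most_specific = []
    for c in all_subsumers:
        strictly_below = (
            d
            for d in all_subsumers
            if d != c and _class_leq(d, c, axioms) and not _class_leq(c, d, axioms)
        )
        if not any(strictly_below):
            most_specific.append(c)
    return all_subsumers, most_specific


def infer_hierarchy(axioms: AxiomSet, defined: Iterable[str]) -> list[tuple[str, str]]:
    """Pairwise subsumption among defined classes; returns the transitive
    reduction of the edges absent from the asserted is_a graph, sorted."""
    pool = sorted(set(defined))
    order = nx.DiGraph()
    order.add_nodes_from(pool)
    for child in pool:
        for parent in pool:
            if child == parent:
                continue
            if _class_leq(child, parent, axioms) and not _class_leq(
                parent, child, axioms
            ):
                order.add_edge(child, parent)
    if not nx.is_directed_acyclic_graph(order):  # pragma: no cover - guarded above
        raise ReasoningError("inferred hierarchy is cyclic")
    reduced = nx.transitive_reduction(order)
    new_edges = [
        (child, parent)
        for child, parent in reduced.edges
        if parent not in axioms.isa_ancestors(child)
    ]
    return sorted(new_edges)


# ---------------------------------------------------------------------------
# Qualifier/bearer consistency
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ConsistencyResult:
    ok: bool
    skipped: bool = False
    quality: str = ""
    bearer: str = ""
    quality_category: Optional[str] = None  # "process" | "object"
    bearer_category: Optional[str] = None
    message: str = ""


def check_qualifier_consistency(
    quality: str, bearer: str, ontologies: Ontology, axioms: Optional[AxiomSet] = None
) -> ConsistencyResult:
    """Check that a PATO quality's bearer category matches the bearer term.

    A process quality (below PATO:0001236) paired with a cellular component
    or cell, or an object quality (below PATO:0001241) paired with a process
    or molecular function, is a violation.  Qualities under neither branch
    yield a skipped check with a logged warning.
    """
    if axioms is None:
        axioms = AxiomSet.from_ontology(ontologies)
    ancestors = axioms.isa_ancestors(quality)
    if PROCESS_QUALITY_ROOT in ancestors:
        q_cat = "process"
    elif OBJECT_QUALITY_ROOT in ancestors:
        q_cat = "object"
    else:
        logger.warning("quality %s has no declared bearer category; check skipped", quality)
        return ConsistencyResult(
            ok=True,
            skipped=True,
            quality=quality,
            bearer=bearer,
            message=f"quality {quality} has no declared bearer category",
        )
    namespace = ontologies.namespace_of(bearer)
    if namespace in _PROCESS_NAMESPACES:
        b_cat = "process"
    elif namespace in _OBJECT_NAMESPACES:
        b_cat = "object"
    else:
        return ConsistencyResult(
            ok=True,
            skipped=True,
            quality=quality,
            bearer=bearer,
            quality_category=q_cat,
            message=f"bearer {bearer} has no process/object namespace",
        )
    ok = q_cat == b_cat
    message = "" if ok else (
        f"{q_cat} quality {quality} cannot inhere in {b_cat} bearer {bearer}"
    )
    return ConsistencyResult(
        ok=ok,
        quality=quality,
        bearer=bearer,
        quality_category=q_cat,
        bearer_category=b_cat,
        message=message,
    )
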