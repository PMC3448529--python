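"""Independent brute-force oracles used to cross-check the reasoner.

The subsumption oracle takes a different route from the production reasoner:
instead of a top-down homomorphism search with path rules, it *saturates* the
specific description tree — materializing reflexive part-of self-loops,
transitive part-of compositions, the has-part/part-of chain, ontology-level
part-of leaves, and is_a-closed atom sets — and then runs a completely naive
exact-relation matcher over the saturated graph.
"""
from __future__ import annotations

import itertools

from eqphen.eq_core import And, Atom, ClassExpression, HAS_PART, PART_OF, Some


class _BruteNode:
    __slots__ = ("atoms", "edges")

    def __init__(self):
        self.atoms: set[str] = set()
        self.edges: set[tuple[str, "_BruteNode"]] = set()


def _build(expr: ClassExpression, node: _BruteNode, all_nodes: list[_BruteNode]) -> None:
    if isinstance(expr, Atom):
        node.atoms.add(expr.curie)
    elif isinstance(expr, Some):
        child = _BruteNode()
        all_nodes.append(child)
        node.edges.add((expr.relation, child))
        _build(expr.filler, child, all_nodes)
    elif isinstance(expr, And):
        for op in expr.operands:
            _build(op, node, all_nodes)
    else:  # pragma: no cover
        raise TypeError(expr)


def _tree(expr: ClassExpression) -> tuple[_BruteNode, list[_BruteNode]]:
    root = _BruteNode()
    nodes = [root]
    _build(expr, root, nodes)
    return root, nodes


def brute_subsumes(general, specific, axioms) -> bool:
    """Saturate the specific tree, then match naively.

    ``axioms`` is the production AxiomSet but only its named-class closures
    (isa_ancestors / ispart_ancestors) and unfold are consumed.
    """
    g_root, _ = _tree(axioms.unfold(general))
    s_root, s_nodes = _tree(axioms.unfold(specific))

    # is_a-closed atom sets
    for node in s_nodes:
        closed = set()
        for atom in node.atoms:
            closed |= axioms.isa_ancestors(atom)
        node.atoms = closed

    # ontology-level part-of leaves: an atom's is_a/part_of ancestors are
    # reachable as parts-whole targets
    leaves = []
    for node in s_nodes:
        for atom in set(node.atoms):
            for target in axioms.ispart_ancestors(atom):
                leaf = _BruteNode()
                leaf.atoms = set(axioms.isa_ancestors(target))
                leaves.append(leaf)
                node.edges.add((PART_OF, leaf))
    s_nodes.extend(leaves)

    # reflexive part-of self-loops
    for node in s_nodes:
        node.edges.add((PART_OF, node))

    # saturate: part-of transitivity and the has-part o part-of chain
    changed = True
    while changed:
        changed = False
        for node in s_nodes:
            new = set()
            for rel, child in node.edges:
                if rel in (PART_OF, HAS_PART):
                    for rel2, grandchild in child.edges:
                        if rel2 == PART_OF:
                            candidate = (rel, grandchild)
                            if candidate not in node.edges:
                                new.add(candidate)
            if new:
                node.edges |= new
                changed = True

    def hom(g: _BruteNode, s: _BruteNode) -> bool:
        if not g.atoms <= s.atoms:
            return False
        return all(
            any(rel2 == rel and hom(gc, sc) for rel2, sc in s.edges)
            for rel, gc in g.edges
        )

    return hom(g_root, s_root)


def brute_pairwise_hierarchy(axioms, defined):
    """O(n^2) inferred-edge oracle: strict pairwise class subsumption via
    brute_subsumes, transitive-reduced with networkx, minus asserted edges."""
    import networkx as nx

    def defs(c):
        if c in axioms.equivalences:
            return [axioms.equivalences[c]]
        return axioms.sufficient_conditions.get(c, [])

    def leq(child, parent):
        if parent in axioms.isa_ancestors(child):
            return True
        child_defs = defs(child)
        if not child_defs:
            return False
        parent_eq = axioms.equivalences.get(parent)
        parent_suf = axioms.sufficient_conditions.get(parent, [])

        def geq_expr(e):
            if parent_eq is not None:
                return brute_subsumes(parent_eq, e, axioms)
            return any(brute_subsumes(d, e, axioms) for d in parent_suf)

        return all(geq_expr(e) for e in child_defs)

    pool = sorted(set(defined))
    graph = nx.DiGraph()
    graph.add_nodes_from(pool)
    for child, parent in itertools.permutations(pool, 2):
        if leq(child, parent) and not leq(parent, child):
            graph.add_edge(child, parent)
    reduced = nx.transitive_reduction(graph)
    return sorted(
        (c, p) for c, p in reduced.edges if p not in axioms.isa_ancestors(c)
    )
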