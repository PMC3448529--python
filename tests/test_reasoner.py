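"""Structural subsumption semantics, classification, hierarchy inference."""
import random

import networkx as nx
import pytest

import eqphen as eq
from eqphen.eq_core import Atom, Some
from eqphen.fixtures import random_expression
from oracles import brute_subsumes, brute_pairwise_hierarchy


def _random_pairs(n, seed=73):
    rng = random.Random(seed)
    return [(random_expression(rng), random_expression(rng)) for _ in range(n)]


def test_formalized_heat_sensitivity_classifies_under_observable(
    merged, qualifier_table, compiled, axioms
):
    equivalences, _ = compiled
    ann = eq.PhenotypeAnnotation("S000029075", "CDC29", "APO:0000147", "APO:0000004")
    expr = eq.formalize_annotation(ann, merged, qualifier_table)
    assert eq.subsumes(equivalences["APO:0000147"], expr, axioms)
    assert not eq.subsumes(expr, equivalences["APO:0000147"], axioms)


def test_subsumption_reflexive_on_random_expressions(axioms, rng):
    for _ in range(200):
        expr = random_expression(rng)
        assert eq.subsumes(expr, expr, axioms)


def test_subsumption_transitive_on_random_expressions(axioms):
    pairs = _random_pairs(400, seed=11)
    exprs = [p for pair in pairs for p in pair]
    hits = 0
    for a, b in pairs:
        if not eq.subsumes(a, b, axioms):
            continue
        for c in exprs[:40]:
            if eq.subsumes(b, c, axioms):
                assert eq.subsumes(a, c, axioms)
                hits += 1
    assert hits > 0  # the check actually exercised chains


def test_part_of_path_semantics(axioms):
    has_part_cell_cycle = Some("has-part", Atom("GO:0022402"))
    # reflexivity: part-of some X subsumes X itself
    assert eq.subsumes(Some("part-of", Atom("GO:0009987")), Atom("GO:0022402"), axioms)
    # chain: has-part absorbs a trailing part-of
    nested = Some("has-part", Some("part-of", Atom("GO:0022402")))
    assert eq.subsumes(has_part_cell_cycle, nested, axioms)
    # named-hierarchy part_of edge: cell cycle process part_of cell cycle
    assert eq.subsumes(Some("part-of", Atom("GO:0007049")), Atom("GO:0022402"), axioms)
    # fixture part_of edge: cellular metabolic process sits inside cellular process
    assert eq.subsumes(
        Some("part-of", Atom("GO:0009987")), Some("part-of", Atom("GO:0044237")), axioms
    )
    # no free ride for other relations
    assert not eq.subsumes(
        Some("has-quality", Atom("GO:0022402")), Atom("GO:0022402"), axioms
    )


def test_agreement_with_brute_force_oracle(axioms):
    disagreements = [
        (eq.render(g), eq.render(s))
        for g, s in _random_pairs(500)
        if eq.subsumes(g, s, axioms) != brute_subsumes(g, s, axioms)
    ]
    assert disagreements == []


def test_monotonicity_under_added_isa_edges(merged, compiled):
    """Adding is_a edges can only create subsumptions, never destroy them."""
    equivalences, sufficient = compiled
    base = eq.AxiomSet.from_ontology(
        merged, equivalences=equivalences, sufficient_conditions=sufficient
    )
    pairs = _random_pairs(200, seed=5)
    before = [eq.subsumes(g, s, base) for g, s in pairs]
    isa_edges = [
        (t.id, parent) for t in merged.terms.values() for parent in t.is_a
    ]
    part_edges = [
        (t.id, target)
        for t in merged.terms.values()
        for rel, target in t.relationships
        if rel == "part_of"
    ]
    extended = eq.AxiomSet(
        equivalences=equivalences,
        sufficient_conditions=sufficient,
        isa_edges=isa_edges + [("GO:0009408", "GO:0009987"), ("GO:0005739", "GO:0005618")],
        part_of_edges=part_edges,
    )
    after = [eq.subsumes(g, s, extended) for g, s in pairs]
    assert all(not b or a for b, a in zip(before, after))


def test_classify_most_specific(merged, qualifier_table, axioms, defined):
    ann = eq.PhenotypeAnnotation("S1", "CDC29", "APO:0000147", "APO:0000004")
    expr = eq.formalize_annotation(ann, merged, qualifier_table)
    all_subsumers, most_specific = eq.classify(expr, axioms, defined)
    assert "APO:0000147" in most_specific
    assert set(most_specific) <= set(all_subsumers)


def test_classify_unknown_atom_has_no_subsumers(axioms, defined):
    assert eq.classify(Atom("GO:0003674"), axioms, defined) == ([], [])


def test_classify_under_cross_species_ontology(catalog, merged, qualifier_table):
    """An autophagy:absent yeast phenotype classifies under an EQ-defined
    'abnormal autophagy' class of another species' ontology, with 'abnormal
    metabolism' as a more general subsumer."""
    demo = eq.merge_ontologies([merged, eq.build_cross_species_demo()])
    equivalences, sufficient = eq.compile_all(demo, catalog.union_definitions)
    axioms = eq.AxiomSet.from_ontology(
        demo, equivalences=equivalences, sufficient_conditions=sufficient
    )
    ann = eq.PhenotypeAnnotation("S000029048", "ATG1", "APO:0000903", "APO:0000005")
    expr = eq.formalize_annotation(ann, demo, eq.default_qualifier_table())
    all_subsumers, most_specific = eq.classify(
        expr, axioms, ["XPO:0000001", "XPO:0000002"]
    )
    assert all_subsumers == ["XPO:0000001", "XPO:0000002"]
    assert most_specific == ["XPO:0000001"]


def test_infer_hierarchy_restructures_taxonomy(axioms, defined):
    edges = eq.infer_hierarchy(axioms, defined)
    assert ("APO:0000023", "APO:0000066") in edges
    assert ("APO:0000094", "APO:0000066") in edges
    # none of the inferred edges are asserted
    for child, parent in edges:
        assert parent not in axioms.isa_ancestors(child)


def test_infer_hierarchy_matches_pairwise_oracle(axioms, defined):
    assert eq.infer_hierarchy(axioms, defined) == brute_pairwise_hierarchy(
        axioms, defined
    )


def test_infer_hierarchy_empty_without_definitions(merged):
    axioms = eq.AxiomSet.from_ontology(merged)
    assert eq.infer_hierarchy(axioms, []) == []


def test_inferred_plus_asserted_edges_acyclic(merged, axioms, defined):
    graph = nx.DiGraph()
    for term in merged.terms.values():
        for parent in term.is_a:
            graph.add_edge(term.id, parent)
    graph.add_edges_from(eq.infer_hierarchy(axioms, defined))
    assert nx.is_directed_acyclic_graph(graph)


def test_definitional_cycle_is_hard_error(merged):
    cyclic = eq.AxiomSet(
        equivalences={
            "APO:0000066": Some("has-part", Atom("APO:0000023")),
            "APO:0000023": Some("has-part", Atom("APO:0000066")),
        }
    )
    with pytest.raises(eq.ReasoningError, match="cycle"):
        eq.subsumes(Atom("APO:0000066"), Atom("APO:0000023"), cyclic)


def test_equivalence_and_sufficient_conditions_conflict_rejected():
    with pytest.raises(eq.ReasoningError):
        eq.AxiomSet(
            equivalences={"APO:0000094": Atom("GO:0009987")},
            sufficient_conditions={"APO:0000094": [Atom("GO:0008152")]},
        )


@pytest.mark.parametrize(
    "quality,bearer,ok",
    [
        ("PATO:0000297", "GO:0022402", True),  # process quality on a process
        ("PATO:0000297", "GO:0005618", False),  # process quality on an object
        ("PATO:0000051", "GO:0005618", True),  # object quality on an object
        ("PATO:0001457", "GO:0005623", False),  # sensitivity on the cell
    ],
)
def test_qualifier_consistency(merged, quality, bearer, ok):
    result = eq.check_qualifier_consistency(quality, bearer, merged)
    assert result.ok is ok
    assert not result.skipped
    if not ok:
        assert quality in result.message and bearer in result.message


def test_qualifier_consistency_skips_uncategorized_quality(merged, caplog):
    with caplog.at_level("WARNING"):
        result = eq.check_qualifier_consistency("PATO:0000461", "GO:0022402", merged)
    assert result.skipped and result.ok
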