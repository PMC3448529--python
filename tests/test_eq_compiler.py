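"""Phene patterns, qualifier composition, annotation formalization."""
import pytest

import eqphen as eq
from eqphen import fixtures as fx
from eqphen.eq_core import And
from eqphen.eq_compiler import PatternCategory, categorize

# The published equivalence/annotation expressions (verbatim mode).
PUBLISHED = {
    "APO:0000053": "phenotype-of some (has-part some (GO:0005618 and has-quality some PATO:0000051))",
    "APO:0000142": "phenotype-of some (has-part some (GO:0005623 and has-quality some PATO:0000117 and during some GO:0031576))",
    "APO:0000066": "phenotype-of some (has-part some (part-of some GO:0009987 and has-quality some PATO:0000001))",
    "APO:0000090": "phenotype-of some (has-part some (GO:0010038 and has-quality some PATO:0001457))",
    "APO:0000087": "phenotype-of some (GO:0042221 and has-quality some (PATO:0001457 and towards some CHEBI:37577))",
}
PUBLISHED_ANNOTATIONS = {
    ("APO:0000147", "APO:0000004", None): (
        "phenotype-of some (has-part some (GO:0009408 and has-quality some "
        "(PATO:0001457 and increased-in-magnitude-relative-to some PATO:0000461)))"
    ),
    ("APO:0000253", "APO:0000250", None): (
        "phenotype-of some (has-part some (GO:0022402 and has-quality some PATO:0000297))"
    ),
    ("APO:0000087", "APO:0000003", "CHEBI:26710"): (
        "phenotype-of some (has-part some (GO:0042221 and has-quality some "
        "(PATO:0001457 and towards some CHEBI:26710)))"
    ),
}


@pytest.mark.parametrize("curie,expected", sorted(PUBLISHED.items()))
def test_compile_definition_verbatim_matches_published(merged, curie, expected):
    expr = eq.compile_definition(merged.get(curie), merged, verbatim=True)
    assert eq.render(expr) == expected


def test_normalized_mode_uses_uniform_has_part(merged):
    """Default output wraps the chemical-resistance pattern in has-part even
    though the published equivalence omits it."""
    expr = eq.compile_definition(merged.get("APO:0000087"), merged, verbatim=False)
    assert eq.render(expr) == (
        "phenotype-of some (has-part some (GO:0042221 and has-quality some "
        "(PATO:0001457 and towards some CHEBI:37577)))"
    )


@pytest.mark.parametrize("key,expected", sorted(PUBLISHED_ANNOTATIONS.items()))
def test_formalize_annotation_verbatim_matches_published(
    merged, qualifier_table, key, expected
):
    observable, qualifier, chemical = key
    ann = eq.PhenotypeAnnotation("S1", "GENE", observable, qualifier, chemical)
    expr = eq.formalize_annotation(ann, merged, qualifier_table, verbatim=True)
    assert eq.render(expr) == expected


def test_triple_annotation_default_mode_applies_magnitude(merged, qualifier_table):
    """Outside verbatim mode the decreased qualifier of a chemical triple is
    composed as a magnitude comparison against normal."""
    ann = eq.PhenotypeAnnotation("S000000649", "G", "APO:0000087", "APO:0000003", "CHEBI:26710")
    rendered = eq.render(eq.formalize_annotation(ann, merged, qualifier_table))
    assert "decreased-in-magnitude-relative-to some PATO:0000461" in rendered
    assert "towards some CHEBI:26710" in rendered


def test_category_assignment(merged):
    cases = {
        "APO:0000053": PatternCategory.OBJECT_MORPHOLOGY,
        "APO:0000142": PatternCategory.TEMPORAL_OBJECT,
        "APO:0000066": PatternCategory.PROCESS,
        "APO:0000147": PatternCategory.DISPOSITION,
        "APO:0000087": PatternCategory.RELATIONAL,
    }
    for curie, expected in cases.items():
        eqdef = merged.get(curie).eq_definition()
        assert categorize(eqdef, merged, curie, {}) is expected
    # the shipped override table reroutes cell cycle progression
    overrides = eq.default_category_overrides()
    eqdef = merged.get("APO:0000253").eq_definition()
    assert categorize(eqdef, merged, "APO:0000253", overrides) is PatternCategory.DISPOSITION


def test_union_definition_compiles_per_disjunct(catalog, merged, axioms):
    term = merged.get("APO:0000094")
    quality, bearers = catalog.union_definitions["APO:0000094"]
    disjuncts = eq.compile_union_definition(term, bearers, quality)
    assert len(disjuncts) == 2
    # anything matching either disjunct classifies under the union class
    for disjunct in disjuncts:
        _, most_specific = eq.classify(disjunct, axioms, ["APO:0000094"])
        assert most_specific == ["APO:0000094"]
    with pytest.raises(eq.CompileError):
        eq.compile_union_definition(term, bearers[:1], quality)


def test_map_qualifier(qualifier_table):
    assert eq.map_qualifier("APO:0000250", qualifier_table).pato_equivalent == "PATO:0000297"
    assert (
        eq.map_qualifier("APO:0000004", qualifier_table).magnitude_modifier
        == "increased-in-magnitude-relative-to"
    )
    with pytest.raises(eq.CompileError, match="unmapped"):
        eq.map_qualifier("APO:9999999", qualifier_table)


def test_formalize_requires_eq_definition(merged, qualifier_table):
    ann = eq.PhenotypeAnnotation("S1", "G", "APO:0000017", "APO:0000004")  # branch root
    with pytest.raises(eq.CompileError, match="APO:0000017"):
        eq.formalize_annotation(ann, merged, qualifier_table)


def test_compile_rejects_definition_without_bearer(merged):
    term = eq.OntologyTerm(
        id="APO:0009999",
        intersection_of=eq.IntersectionDefinition("PATO:0000001", ()),
    )
    with pytest.raises(eq.CompileError, match="APO:0009999"):
        eq.compile_definition(term, merged)


def test_combine_genotype(merged, qualifier_table, axioms):
    annotations = [
        a
        for a in eq.read_phenotype_annotations(fx.sample_phenotype_table())
        if a.genotype_id == "S000029075"
    ]
    exprs = [eq.formalize_annotation(a, merged, qualifier_table) for a in annotations]
    combined = eq.combine_genotype(exprs)
    assert isinstance(combined, And) and len(combined.operands) == 3
    # the intersection is subsumed by each conjunct
    for expr in exprs:
        assert eq.subsumes(expr, combined, axioms)
    assert eq.combine_genotype(exprs[:1]) is exprs[0]
    with pytest.raises(eq.CompileError):
        eq.combine_genotype([])


def test_substituted_annotations_subsumed_by_bare_observable(
    merged, qualifier_table, compiled, axioms
):
    """Plain-substitution qualifiers specialize the quality, so every such
    annotation falls under its observable's own compiled class."""
    equivalences, _ = compiled
    substitutions = [
        q for q, rule in qualifier_table.items() if rule.pato_equivalent is not None
    ]
    checked = 0
    for observable, definition in equivalences.items():
        term = merged.get(observable)
        if term is None or term.namespace != "observable":
            continue
        for qualifier in substitutions:
            ann = eq.PhenotypeAnnotation("S1", "G", observable, qualifier)
            expr = eq.formalize_annotation(ann, merged, qualifier_table)
            assert eq.subsumes(definition, expr, axioms), (observable, qualifier)
            checked += 1
    assert checked > 10


def test_compilation_is_deterministic(merged, catalog):
    first = {
        c: eq.render(e) for c, e in eq.compile_all(merged, catalog.union_definitions)[0].items()
    }
    second = {
        c: eq.render(e) for c, e in eq.compile_all(merged, catalog.union_definitions)[0].items()
    }
    assert first == second
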