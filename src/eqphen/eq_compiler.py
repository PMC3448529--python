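"""Compile EQ definitions and phenotype annotations into class expressions.

Each observable's EQ definition (quality + bearer entity + optional during /
towards differentia) is pushed through a *phene pattern* chosen by category:

object-morphology
    ``phenotype-of some (has-part some (bearer and has-quality some Q))``
temporal-object
    as above with ``and during some stage`` appended inside the bearer
    conjunction
process
    ``phenotype-of some (has-part some (part-of some bearer and
    has-quality some Q))`` — the part-of step buys inferences from the
    entity ontology's parthood structure (part-of being reflexive, the
    simple bearer form still classifies under process-pattern classes)
disposition
    structurally the object pattern over a process bearer (dispositions such
    as resistances are carried by sensitivity-of-a-process qualities; the
    has-disposition/has-function distinction is deliberately not modelled)
relational
    the object pattern with the quality refined to
    ``(Q and towards some chemical)``

Category is a pure function of the EQ definition and the bearer's namespace
(towards => relational, during => temporal-object, quality under sensitivity
of a process => disposition, process/function bearer => process, otherwise
object-morphology), overridable per term through a config table.

Qualifiers compose in one of two ways: a plain PATO substitution (arrested ->
PATO:0000297) replaces the quality atom, while the comparative qualifiers
wrap it as ``(Q and increased-in-magnitude-relative-to some PATO:0000461)``
(and symmetrically for decreased).  A triple annotation's chemical attaches
as ``towards`` on the quality.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum
from importlib import resources
from typing import Mapping, Optional, Sequence

from .eq_core import (
    And,
    Atom,
    ClassExpression,
    EQDefinition,
    EqphenError,
    EXPRESSION_RELATIONS,
    HAS_PART,
    HAS_QUALITY,
    DURING,
    NORMAL_QUALITY,
    PART_OF,
    PHENOTYPE_OF,
    Some,
    TOWARDS,
    canonicalize,
    is_curie,
)
from .obo_io import Ontology, OntologyTerm, PhenotypeAnnotation

logger = logging.getLogger(__name__)

__all__ = [
    "CompileError",
    "PatternCategory",
    "QualifierRule",
    "QualifierMapping",
    "load_qualifier_table",
    "default_qualifier_table",
    "load_category_overrides",
    "default_category_overrides",
    "load_union_table",
    "categorize",
    "compile_definition",
    "compile_union_definition",
    "compile_all",
    "map_qualifier",
    "formalize_annotation",
    "combine_genotype",
    "SENSITIVITY_QUALITY",
    "VERBATIM_OMITS_HAS_PART",
]


class CompileError(EqphenError):
    """An EQ definition or annotation that cannot be compiled."""


#: PATO "sensitivity of a process"; qualities under this branch mark
#: dispositional phenotypes (resistances, sensitivities).
SENSITIVITY_QUALITY = "PATO:0001457"

#: Terms whose published equivalence omits the has-part step; reproduced only
#: in verbatim mode (default output is the uniform has-part form).
VERBATIM_OMITS_HAS_PART = frozenset({"APO:0000087"})

_PROCESS_NAMESPACES = frozenset({"biological_process", "molecular_function"})


class PatternCategory(str, Enum):
    OBJECT_MORPHOLOGY = "object-morphology"
    TEMPORAL_OBJECT = "temporal-object"
    PROCESS = "process"
    DISPOSITION = "disposition"
    RELATIONAL = "relational"


# ---------------------------------------------------------------------------
# Config tables (qualifier mapping, category overrides, union definitions)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class QualifierRule:
    """Exactly one strategy applies: a PATO substitution or a magnitude
    modifier relation."""

    pato_equivalent: Optional[str] = None
    magnitude_modifier: Optional[str] = None

    def __post_init__(self) -> None:
        if (self.pato_equivalent is None) == (self.magnitude_modifier is None):
            raise ValueError(
                "exactly one of pato_equivalent / magnitude_modifier must be set"
            )


QualifierMapping = Mapping[str, QualifierRule]


def load_qualifier_table(text: str) -> dict[str, QualifierRule]:
    """Parse the qualifier config: three tab-separated columns
    ``qualifier_id  strategy  value`` with strategy ``substitute`` (value a
    PATO CURIE) or ``magnitude`` (value a magnitude relation)."""
    table: dict[str, QualifierRule] = {}
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#") or line.startswith("!"):
            continue
        fields = line.split("\t")
        if len(fields) != 3:
            raise CompileError(f"qualifier table line {lineno}: expected 3 columns")
        qualifier, strategy, value = fields
        if strategy == "substitute":
            if not is_curie(value):
                raise CompileError(
                    f"qualifier table line {lineno}: substitution value must be a CURIE"
                )
            table[qualifier] = QualifierRule(pato_equivalent=value)
        elif strategy == "magnitude":
            if value not in EXPRESSION_RELATIONS:
                raise CompileError(
                    f"qualifier table line {lineno}: unknown magnitude relation {value!r}"
                )
            table[qualifier] = QualifierRule(magnitude_modifier=value)
        else:
            raise CompileError(
                f"qualifier table line {lineno}: unknown strategy {strategy!r}"
            )
    return table


def _read_data(name: str) -> str:
    return resources.files("eqphen.data").joinpath(name).read_text(encoding="utf-8")


def default_qualifier_table() -> dict[str, QualifierRule]:
    """The qualifier mapping shipped with the package (data/qualifiers.tsv)."""
    return load_qualifier_table(_read_data("qualifiers.tsv"))


def load_category_overrides(text: str) -> dict[str, PatternCategory]:
    """Two tab-separated columns ``term_id  category``."""
    overrides: dict[str, PatternCategory] = {}
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#") or line.startswith("!"):
            continue
        fields = line.split("\t")
        if len(fields) != 2:
            raise CompileError(f"category table line {lineno}: expected 2 columns")
        term_id, category = fields
        try:
            overrides[term_id] = PatternCategory(category)
        except ValueError as exc:
            raise CompileError(
                f"category table line {lineno}: unknown category {category!r}"
            ) from exc
    return overrides


def default_category_overrides() -> dict[str, PatternCategory]:
    return load_category_overrides(_read_data("categories.tsv"))


def load_union_table(text: str) -> dict[str, tuple[str, tuple[str, ...]]]:
    """Union definitions: ``term_id  quality_id  bearer1|bearer2|...``."""
    unions: dict[str, tuple[str, tuple[str, ...]]] = {}
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#") or line.startswith("!"):
            continue
        fields = line.split("\t")
        if len(fields) != 3:
            raise CompileError(f"union table line {lineno}: expected 3 columns")
        term_id, quality, bearers = fields
        unions[term_id] = (quality, tuple(bearers.split("|")))
    return unions


# ---------------------------------------------------------------------------
# Category assignment
# ---------------------------------------------------------------------------


def categorize(
    eq: EQDefinition,
    ontologies: Ontology,
    term_id: Optional[str] = None,
    overrides: Optional[Mapping[str, PatternCategory]] = None,
) -> PatternCategory:
    """Assign the phene-pattern category for an EQ definition."""
    if overrides and term_id is not None and term_id in overrides:
        return overrides[term_id]
    if eq.towards is not None:
        return PatternCategory.RELATIONAL
    if eq.during is not None:
        return PatternCategory.TEMPORAL_OBJECT
    if _is_sensitivity_quality(eq.quality, ontologies):
        return PatternCategory.DISPOSITION
    namespace = ontologies.namespace_of(eq.bearer)
    if namespace in _PROCESS_NAMESPACES:
        return PatternCategory.PROCESS
    return PatternCategory.OBJECT_MORPHOLOGY


def _is_a_descendant(child: str, ancestor: str, ontologies: Ontology) -> bool:
    """Reflexive-transitive is_a reachability within the loaded terms."""
    seen: set[str] = set()
    stack = [child]
    while stack:
        current = stack.pop()
        if current == ancestor:
            return True
        if current in seen:
            continue
        seen.add(current)
        term = ontologies.get(current)
        if term is not None:
            stack.extend(term.is_a)
    return False


def _is_sensitivity_quality(quality: str, ontologies: Ontology) -> bool:
    return _is_a_descendant(quality, SENSITIVITY_QUALITY, ontologies)


# ---------------------------------------------------------------------------
# Pattern construction
# ---------------------------------------------------------------------------


def _build_pattern(
    eq: EQDefinition,
    category: PatternCategory,
    quality_expr: Optional[ClassExpression] = None,
    omit_has_part: bool = False,
) -> ClassExpression:
    """Assemble the pattern.  Operand order mirrors the published listings
    (bearer, has-quality, during) and is *not* canonical-sorted, so renderings
    match the printed forms; canonicalize() is available when a sort-stable
    form is needed."""
    if quality_expr is None:
        quality_expr = Atom(eq.quality)
        if category is PatternCategory.RELATIONAL and eq.towards is not None:
            quality_expr = And([quality_expr, Some(TOWARDS, Atom(eq.towards))])
    bearer: ClassExpression = Atom(eq.bearer)
    if category is PatternCategory.PROCESS:
        bearer = Some(PART_OF, bearer)
    operands: list[ClassExpression] = [bearer, Some(HAS_QUALITY, quality_expr)]
    if category is PatternCategory.TEMPORAL_OBJECT and eq.during is not None:
        operands.append(Some(DURING, Atom(eq.during)))
    body = And(operands)
    if omit_has_part:
        return Some(PHENOTYPE_OF, body)
    return Some(PHENOTYPE_OF, Some(HAS_PART, body))


def compile_definition(
    term: OntologyTerm,
    ontologies: Ontology,
    verbatim: bool = False,
    overrides: Optional[Mapping[str, PatternCategory]] = None,
) -> ClassExpression:
    """Compile a term's EQ definition through its phene pattern.

    With ``verbatim=True`` the flagged exceptions reproduce their published
    form (APO:0000087 omits the has-part step) instead of the normalized
    uniform pattern.
    """
    eq = term.eq_definition()
    if eq is None:
        missing = "intersection_of block" if term.intersection_of is None else "bearer"
        raise CompileError(f"term {term.id} has no compilable EQ definition ({missing} missing)")
    if overrides is None:
        overrides = default_category_overrides()
    category = categorize(eq, ontologies, term.id, overrides)
    omit = verbatim and term.id in VERBATIM_OMITS_HAS_PART
    return _build_pattern(eq, category, omit_has_part=omit)


def compile_union_definition(
    term: OntologyTerm, bearers: Sequence[str], quality: str
) -> list[ClassExpression]:
    """One process-pattern expression per disjunct of a union-defined class.

    Each returned expression is a *sufficient condition* (expression ⊑ term),
    not an equivalence; anything matching either disjunct classifies under
    the term.
    """
    if len(bearers) < 2:
        raise CompileError(
            f"term {term.id}: union definition needs at least two bearers"
        )
    return [
        _build_pattern(
            EQDefinition(quality=quality, bearer=bearer), PatternCategory.PROCESS
        )
        for bearer in bearers
    ]


def compile_all(
    ontologies: Ontology,
    unions: Optional[Mapping[str, tuple[str, Sequence[str]]]] = None,
    verbatim: bool = False,
    overrides: Optional[Mapping[str, PatternCategory]] = None,
) -> tuple[dict[str, ClassExpression], dict[str, list[ClassExpression]]]:
    """Compile every term carrying an EQ definition plus all union entries.

    Returns (equivalences, sufficient_conditions) keyed by CURIE, the shape
    the reasoner's axiom set takes.
    """
    equivalences: dict[str, ClassExpression] = {}
    for curie in sorted(ontologies.terms):
        term = ontologies.terms[curie]
        if term.eq_definition() is not None:
            equivalences[curie] = compile_definition(
                term, ontologies, verbatim=verbatim, overrides=overrides
            )
    sufficient: dict[str, list[ClassExpression]] = {}
    for term_id, (quality, bearers) in (unions or {}).items():
        term = ontologies.get(term_id) or OntologyTerm(id=term_id)
        if len(bearers) == 1:
            equivalences[term_id] = _build_pattern(
                EQDefinition(quality=quality, bearer=bearers[0]),
                PatternCategory.PROCESS,
            )
        else:
            sufficient[term_id] = compile_union_definition(term, bearers, quality)
    return equivalences, sufficient


# ---------------------------------------------------------------------------
# Qualifier application and annotation formalization
# ---------------------------------------------------------------------------


def map_qualifier(qualifier: str, table: QualifierMapping) -> QualifierRule:
    """Look up the composition strategy for an APO qualifier."""
    rule = table.get(qualifier)
    if rule is None:
        known = ", ".join(sorted(table)) or "(none)"
        raise CompileError(
            f"unmapped qualifier {qualifier}; known qualifiers: {known}"
        )
    return rule


def formalize_annotation(
    ann: PhenotypeAnnotation,
    ontologies: Ontology,
    table: QualifierMapping,
    verbatim: bool = False,
    overrides: Optional[Mapping[str, PatternCategory]] = None,
) -> ClassExpression:
    """Turn one observable/qualifier(/chemical) annotation into an expression.

    Starting from the observable's EQ definition, a substitution qualifier
    replaces the quality atom when it refines it (arrested for a generic
    process quality) and is conjoined with it otherwise (abnormal alongside
    shape), so the qualified annotation always stays below its bare
    observable; a magnitude qualifier wraps the quality as
    ``(Q and modifier some PATO:0000461)``; a triple's chemical attaches (or
    specializes the definition's) ``towards`` filler.  The result is compiled
    through the observable's pattern category.

    In verbatim mode a triple annotation drops the magnitude modifier,
    mirroring the published expression for chemical-resistance triples.
    """
    term = ontologies.get(ann.observable)
    eq = term.eq_definition() if term is not None else None
    if eq is None:
        raise CompileError(
            f"observable {ann.observable} has no EQ definition; annotation for "
            f"genotype {ann.genotype_id} cannot be formalized"
        )
    rule = map_qualifier(ann.qualifier, table)
    if ann.chemical is not None:
        eq = EQDefinition(
            quality=eq.quality, bearer=eq.bearer, during=eq.during, towards=ann.chemical
        )
    if overrides is None:
        overrides = default_category_overrides()
    category = categorize(eq, ontologies, ann.observable, overrides)

    quality_atom: ClassExpression = Atom(eq.quality)
    refinements: list[ClassExpression] = []
    if rule.pato_equivalent is not None:
        if _is_a_descendant(rule.pato_equivalent, eq.quality, ontologies):
            # the substitution refines the definition quality: replace it
            quality_atom = Atom(rule.pato_equivalent)
        else:
            # incomparable qualities (e.g. abnormal vs shape): compose, so the
            # qualified annotation still falls under its bare observable
            refinements.append(Atom(rule.pato_equivalent))
    if eq.towards is not None:
        refinements.append(Some(TOWARDS, Atom(eq.towards)))
    if rule.magnitude_modifier is not None and not (verbatim and ann.chemical):
        refinements.append(Some(rule.magnitude_modifier, Atom(NORMAL_QUALITY)))
    quality_expr: ClassExpression = (
        And([quality_atom, *refinements]) if refinements else quality_atom
    )
    return _build_pattern(eq, category, quality_expr=quality_expr)


def combine_genotype(exprs: Sequence[ClassExpression]) -> ClassExpression:
    """Conjoin a genotype's phenotype expressions by class intersection
    (canonicalized); a single expression is returned unchanged."""
    exprs = list(exprs)
    if not exprs:
        raise CompileError("cannot combine an empty list of phenotype expressions")
    if len(exprs) == 1:
        return exprs[0]
    return canonicalize(And(exprs))
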