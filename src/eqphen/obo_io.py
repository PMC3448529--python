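"""Read and write the OBO 1.2 flat-file subset and tabular annotation formats.

The OBO dialect supported here covers exactly the clause types a logical
entity-quality definition needs: ``id``, ``name``, ``namespace``, ``is_a``,
``relationship``, ``intersection_of`` and ``is_obsolete``.  Every other tag
(``def``, ``synonym``, ``xref``, ...) is preserved verbatim as an opaque
passthrough line so that a parse/write cycle is lossless.  ``!`` comments are
stripped from recognized clause lines before interpretation.

Two tabular dialects are defined alongside:

* phenotype annotations — six tab-separated columns
  ``genotype_id  gene_id  observable_id  qualifier_id  chemical_id  condition``
  with a mandatory header; ``chemical_id`` empty for pair (observable +
  qualifier) annotations and a ChEBI CURIE for triples; ``condition`` free
  text carried but never interpreted;
* gene-to-GO annotations — three columns ``gene_id  go_id  aspect`` with
  aspect one of P (process), F (function), C (component).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional

from .eq_core import (
    EqphenError,
    EQDefinition,
    DURING,
    INHERES_IN,
    TOWARDS,
    PART_OF,
    RELATION_CHAINS,
    is_curie,
)

logger = logging.getLogger(__name__)

__all__ = [
    "OboFormatError",
    "AnnotationFormatError",
    "IntersectionDefinition",
    "OntologyTerm",
    "RelationProperties",
    "Ontology",
    "PhenotypeAnnotation",
    "GeneGoAnnotation",
    "parse_obo",
    "write_obo",
    "merge_ontologies",
    "read_phenotype_annotations",
    "read_gene_go_annotations",
]


class OboFormatError(EqphenError):
    """Malformed OBO document (duplicate ids, bad intersection_of blocks...)."""


class AnnotationFormatError(EqphenError):
    """Malformed annotation table; message carries the 1-based line number."""


@dataclass(frozen=True)
class IntersectionDefinition:
    """A logical (genus + differentia) definition from ``intersection_of``
    clauses: exactly one genus CURIE plus zero or more (relation, CURIE)
    differentia, in source order."""

    genus: str
    differentia: tuple[tuple[str, str], ...] = ()


@dataclass
class OntologyTerm:
    id: str
    name: str = ""
    namespace: str = ""
    is_a: list[str] = field(default_factory=list)
    relationships: list[tuple[str, str]] = field(default_factory=list)
    intersection_of: Optional[IntersectionDefinition] = None
    is_obsolete: bool = False
    #: unrecognized tag lines, preserved verbatim for lossless round-trips
    extra_lines: list[str] = field(default_factory=list)

    def eq_definition(self) -> Optional[EQDefinition]:
        """Lift the intersection_of block into an EQ definition, if present.

        The genus is the quality; ``inheres_in`` names the bearer entity;
        ``during`` and ``towards`` map to the optional differentia.
        """
        if self.intersection_of is None:
            return None
        bearer = during = towards = None
        for rel, target in self.intersection_of.differentia:
            if rel == INHERES_IN:
                bearer = target
            elif rel == DURING:
                during = target
            elif rel == TOWARDS:
                towards = target
            else:
                logger.warning(
                    "term %s: unsupported EQ differentium relation %r", self.id, rel
                )
        if bearer is None:
            return None
        return EQDefinition(
            quality=self.intersection_of.genus,
            bearer=bearer,
            during=during,
            towards=towards,
        )


@dataclass(frozen=True)
class RelationProperties:
    transitive: bool = False
    reflexive: bool = False


def _default_relation_declarations() -> dict[str, RelationProperties]:
    return {PART_OF: RelationProperties(transitive=True, reflexive=True)}


@dataclass
class Ontology:
    """A term store with relation property declarations and chains.

    ``part-of`` is declared transitive and reflexive by default and the
    mereological chain (has-part, part-of) -> has-part is registered; both can
    be extended per ontology.
    """

    terms: dict[str, OntologyTerm] = field(default_factory=dict)
    relation_declarations: dict[str, RelationProperties] = field(
        default_factory=_default_relation_declarations
    )
    chains: list[tuple[str, str, str]] = field(
        default_factory=lambda: list(RELATION_CHAINS)
    )
    #: count of non-[Term] stanzas skipped during parsing
    skipped_stanzas: int = 0

    def __contains__(self, curie: str) -> bool:
        return curie in self.terms

    def get(self, curie: str) -> Optional[OntologyTerm]:
        return self.terms.get(curie)

    def namespace_of(self, curie: str) -> Optional[str]:
        term = self.terms.get(curie)
        return term.namespace if term is not None else None

    def dangling_references(self) -> set[str]:
        """CURIEs referenced by is_a/relationship/intersection_of clauses that
        do not resolve to a loaded term."""
        dangling: set[str] = set()
        for term in self.terms.values():
            refs = list(term.is_a)
            refs.extend(target for _, target in term.relationships)
            if term.intersection_of is not None:
                refs.append(term.intersection_of.genus)
                refs.extend(t for _, t in term.intersection_of.differentia)
            dangling.update(r for r in refs if r not in self.terms)
        return dangling


# ---------------------------------------------------------------------------
# OBO parsing
# ---------------------------------------------------------------------------

_KNOWN_TAGS = {"id", "name", "namespace", "is_a", "relationship", "is_obsolete"}


def _strip_comment(value: str) -> str:
    return value.split("!", 1)[0].strip()


def _split_stanzas(document: str) -> tuple[list[str], list[list[str]]]:
    """Split into (header lines, stanzas); a stanza starts at a ``[...]`` line."""
    header: list[str] = []
    stanzas: list[list[str]] = []
    current: Optional[list[str]] = None
    for raw in document.splitlines():
        line = raw.rstrip()
        if line.startswith("[") and line.endswith("]"):
            current = [line]
            stanzas.append(current)
        elif current is None:
            header.append(line)
        else:
            current.append(line)
    return header, stanzas


def _parse_term_stanza(lines: list[str]) -> OntologyTerm:
    term_id: Optional[str] = None
    name = ""
    namespace = ""
    is_a: list[str] = []
    relationships: list[tuple[str, str]] = []
    genus_clauses: list[str] = []
    differentia: list[tuple[str, str]] = []
    saw_intersection = False
    is_obsolete = False
    extra: list[str] = []

    for line in lines[1:]:
        if not line.strip() or line.lstrip().startswith("!"):
            continue
        if ":" not in line:
            extra.append(line)
            continue
        tag, _, value = line.partition(":")
        tag = tag.strip()
        if tag not in _KNOWN_TAGS and tag != "intersection_of":
            extra.append(line)
            continue
        value = _strip_comment(value)
        if tag == "id":
            term_id = value
        elif tag == "name":
            name = value
        elif tag == "namespace":
            namespace = value
        elif tag == "is_a":
            is_a.append(value)
        elif tag == "relationship":
            parts = value.split()
            if len(parts) != 2:
                raise OboFormatError(f"malformed relationship clause: {line!r}")
            relationships.append((parts[0], parts[1]))
        elif tag == "intersection_of":
            saw_intersection = True
            parts = value.split()
            if len(parts) == 1:
                genus_clauses.append(parts[0])
            elif len(parts) == 2:
                differentia.append((parts[0], parts[1]))
            else:
                raise OboFormatError(f"malformed intersection_of clause: {line!r}")
        elif tag == "is_obsolete":
            is_obsolete = value.lower() == "true"

    if term_id is None:
        raise OboFormatError("[Term] stanza without an id clause")
    intersection: Optional[IntersectionDefinition] = None
    if saw_intersection:
        if len(genus_clauses) != 1:
            raise OboFormatError(
                f"term {term_id}: intersection_of block must have exactly one "
                f"genus clause, found {len(genus_clauses)}"
            )
        intersection = IntersectionDefinition(genus_clauses[0], tuple(differentia))
        if is_obsolete:
            raise OboFormatError(
                f"term {term_id}: obsolete terms may not carry an intersection_of"
            )
    return OntologyTerm(
        id=term_id,
        name=name,
        namespace=namespace,
        is_a=is_a,
        relationships=relationships,
        intersection_of=intersection,
        is_obsolete=is_obsolete,
        extra_lines=extra,
    )


def parse_obo(document: str) -> Ontology:
    """Parse an OBO 1.2 flat-file document.

    Stanzas other than ``[Term]`` are skipped with a logged warning and
    counted on :attr:`Ontology.skipped_stanzas`.  Duplicate term ids and
    malformed intersection_of blocks (zero or multiple genus clauses) are hard
    errors.  Dangling cross-references are tolerated and reported by
    :meth:`Ontology.dangling_references`, since EQ definitions routinely point
    into ontologies outside the loaded set.
    """
    _, stanzas = _split_stanzas(document)
    ontology = Ontology()
    for stanza in stanzas:
        if stanza[0] != "[Term]":
            logger.warning("skipping %s stanza", stanza[0])
            ontology.skipped_stanzas += 1
            continue
        term = _parse_term_stanza(stanza)
        if term.id in ontology.terms:
            raise OboFormatError(f"duplicate term id: {term.id}")
        ontology.terms[term.id] = term
    dangling = ontology.dangling_references()
    if dangling:
        logger.info(
            "ontology has %d dangling references: %s",
            len(dangling),
            ", ".join(sorted(dangling)[:10]),
        )
    return ontology


# ---------------------------------------------------------------------------
# OBO writing
# ---------------------------------------------------------------------------


def write_obo(ontology: Ontology) -> str:
    """Serialize deterministically: terms sorted by CURIE; within a stanza the
    clause order is id, name, namespace, is_a (sorted), intersection_of (genus
    first), relationship (sorted), is_obsolete, then passthrough lines.
    Byte-identical output for equal inputs."""
    out: list[str] = ["format-version: 1.2", ""]
    for curie in sorted(ontology.terms):
        term = ontology.terms[curie]
        out.append("[Term]")
        out.append(f"id: {term.id}")
        if term.name:
            out.append(f"name: {term.name}")
        if term.namespace:
            out.append(f"namespace: {term.namespace}")
        for parent in sorted(term.is_a):
            out.append(f"is_a: {parent}")
        if term.intersection_of is not None:
            out.append(f"intersection_of: {term.intersection_of.genus}")
            for rel, target in term.intersection_of.differentia:
                out.append(f"intersection_of: {rel} {target}")
        for rel, target in sorted(term.relationships):
            out.append(f"relationship: {rel} {target}")
        if term.is_obsolete:
            out.append("is_obsolete: true")
        out.extend(term.extra_lines)
        out.append("")
    return "\n".join(out)


def merge_ontologies(ontologies: Iterable[Ontology]) -> Ontology:
    """Merge term stores into one namespace-partitioned store.

    Duplicate CURIEs across inputs are a hard error; relation declarations and
    chains are unioned.
    """
    merged = Ontology()
    for ont in ontologies:
        for curie, term in ont.terms.items():
            if curie in merged.terms:
                raise OboFormatError(f"duplicate term id across ontologies: {curie}")
            merged.terms[curie] = term
        merged.relation_declarations.update(ont.relation_declarations)
        for chain in ont.chains:
            if chain not in merged.chains:
                merged.chains.append(chain)
    return merged


# ---------------------------------------------------------------------------
# Annotation tables
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PhenotypeAnnotation:
    """One genotype-phenotype record: observable + qualifier (a *pair*), with
    an optional chemical making it a *triple*."""

    genotype_id: str
    gene_id: str
    observable: str
    qualifier: str
    chemical: Optional[str] = None
    condition: Optional[str] = None


@dataclass(frozen=True)
class GeneGoAnnotation:
    gene_id: str
    go_id: str
    aspect: str  # P | F | C


PHENOTYPE_COLUMNS = (
    "genotype_id",
    "gene_id",
    "observable_id",
    "qualifier_id",
    "chemical_id",
    "condition",
)
GOA_COLUMNS = ("gene_id", "go_id", "aspect")
_ASPECTS = frozenset({"P", "F", "C"})


def _iter_records(table: str, n_columns: int, what: str):
    header_seen = False
    for lineno, raw in enumerate(table.splitlines(), start=1):
        if not raw.strip() or raw.startswith("!"):
            continue
        if not header_seen:
            header_seen = True
            continue
        fields = raw.split("\t")
        if len(fields) != n_columns:
            raise AnnotationFormatError(
                f"line {lineno}: expected {n_columns} tab-separated columns "
                f"in {what}, found {len(fields)}"
            )
        yield lineno, fields
    if not header_seen:
        raise AnnotationFormatError(f"{what}: missing header line")


def read_phenotype_annotations(table: str) -> list[PhenotypeAnnotation]:
    """Read the six-column phenotype annotation dialect, in file order.

    Lines starting with ``!`` are comments; an empty chemical_id column means
    the annotation is an observable/qualifier pair.
    """
    annotations: list[PhenotypeAnnotation] = []
    for lineno, fields in _iter_records(table, 6, "phenotype annotation table"):
        genotype_id, gene_id, observable, qualifier, chemical, condition = fields
        for col, value in (("observable", observable), ("qualifier", qualifier)):
            if not is_curie(value):
                raise AnnotationFormatError(
                    f"line {lineno}: {col} column is not a CURIE: {value!r}"
                )
        chemical = chemical.strip()
        if chemical and not is_curie(chemical):
            raise AnnotationFormatError(
                f"line {lineno}: chemical column is not a CURIE: {chemical!r}"
            )
        annotations.append(
            PhenotypeAnnotation(
                genotype_id=genotype_id,
                gene_id=gene_id,
                observable=observable,
                qualifier=qualifier,
                chemical=chemical or None,
                condition=condition.strip() or None,
            )
        )
    return annotations


def read_gene_go_annotations(table: str) -> list[GeneGoAnnotation]:
    """Read the three-column gene-to-GO table, duplicates preserved
    (deduplication is the recovery comparator's job)."""
    annotations: list[GeneGoAnnotation] = []
    for lineno, fields in _iter_records(table, 3, "gene-GO annotation table"):
        gene_id, go_id, aspect = fields
        if not is_curie(go_id):
            raise AnnotationFormatError(
                f"line {lineno}: go_id column is not a CURIE: {go_id!r}"
            )
        if aspect not in _ASPECTS:
            raise AnnotationFormatError(
                f"line {lineno}: unknown aspect code {aspect!r} (expected P, F or C)"
            )
        annotations.append(GeneGoAnnotation(gene_id, go_id, aspect))
    return annotations
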