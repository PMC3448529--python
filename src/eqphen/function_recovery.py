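"""Gene-function recovery from formalized phenotypes.

The hypothesis under test: the GO classes buried in a gene's formalized
phenotype expressions point at the gene's function.  The analysis extracts
every GO atom from the expressions, then compares them per GO aspect
(P = biological process, F = molecular function, C = cellular component)
against the gene's curated GO annotations.  Because phenotype bearers are
deliberately high-level classes, an exact-match comparison would be nearly
vacuous; the default rule counts an existing annotation (g, t) as *recovered*
when some predicted term p for g equals t or is related to it by ancestry in
the is_a ∪ part_of closure (either direction).  Predicted terms that recover
nothing for their gene are emitted as novel candidate annotations.
"""
from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence, Union

from .eq_core import And, Atom, ClassExpression, Some
from .obo_io import GeneGoAnnotation, Ontology, PhenotypeAnnotation
from .eq_compiler import (
    CompileError,
    PatternCategory,
    QualifierMapping,
    formalize_annotation,
)
from .reasoner import AxiomSet

logger = logging.getLogger(__name__)

__all__ = [
    "AspectCounts",
    "NovelCandidate",
    "RecoveryReport",
    "extract_go_terms",
    "predictions_from_annotations",
    "compare_to_goa",
    "write_report",
    "read_report",
]

ASPECTS = ("P", "F", "C")


@dataclass(frozen=True)
class AspectCounts:
    recovered: int = 0
    total: int = 0

    @property
    def percentage(self) -> Optional[float]:
        """recovered/total in percent; None for an empty aspect."""
        if self.total == 0:
            return None
        return 100.0 * self.recovered / self.total


@dataclass(frozen=True)
class NovelCandidate:
    gene_id: str
    go_id: str
    genotype_ids: tuple[str, ...] = ()


@dataclass
class RecoveryReport:
    aspects: dict[str, AspectCounts] = field(
        default_factory=lambda: {a: AspectCounts() for a in ASPECTS}
    )
    novel_candidates: list[NovelCandidate] = field(default_factory=list)


# ---------------------------------------------------------------------------
# GO-term extraction
# ---------------------------------------------------------------------------


def extract_go_terms(exprs: Iterable[ClassExpression]) -> list[str]:
    """All GO-prefixed atoms anywhere in the expressions (bearers, during
    stages, nested fillers), deduplicated and sorted by CURIE."""
    found: set[str] = set()
    stack: list[ClassExpression] = list(exprs)
    while stack:
        expr = stack.pop()
        if isinstance(expr, Atom):
            if expr.curie.startswith("GO:"):
                found.add(expr.curie)
        elif isinstance(expr, Some):
            stack.append(expr.filler)
        elif isinstance(expr, And):
            stack.extend(expr.operands)
    return sorted(found)


def predictions_from_annotations(
    annotations: Sequence[PhenotypeAnnotation],
    ontologies: Ontology,
    table: QualifierMapping,
    overrides: Optional[Mapping[str, PatternCategory]] = None,
) -> tuple[dict[str, dict[str, set[str]]], list[PhenotypeAnnotation]]:
    """Formalize annotations and collect predicted GO terms per gene.

    Returns (predictions, unformalizable) where predictions maps
    gene_id -> {go_id -> supporting genotype ids}.  Annotations whose
    observable has no EQ definition are returned, not raised.
    """
    predictions: dict[str, dict[str, set[str]]] = defaultdict(lambda: defaultdict(set))
    unformalizable: list[PhenotypeAnnotation] = []
    for ann in annotations:
        try:
            expr = formalize_annotation(ann, ontologies, table, overrides=overrides)
        except CompileError:
            unformalizable.append(ann)
            continue
        for go_id in extract_go_terms([expr]):
            predictions[ann.gene_id][go_id].add(ann.genotype_id)
    return {g: dict(t) for g, t in predictions.items()}, unformalizable


# ---------------------------------------------------------------------------
# Comparison against curated GO annotations
# ---------------------------------------------------------------------------

Predicted = Mapping[str, Union[Iterable[str], Mapping[str, Iterable[str]]]]


def _normalize_predictions(predicted: Predicted) -> dict[str, dict[str, tuple[str, ...]]]:
    normalized: dict[str, dict[str, tuple[str, ...]]] = {}
    for gene, terms in predicted.items():
        if isinstance(terms, Mapping):
            normalized[gene] = {
                t: tuple(sorted(genotypes)) for t, genotypes in terms.items()
            }
        else:
            normalized[gene] = {t: () for t in terms}
    return normalized


def compare_to_goa(
    predicted: Predicted,
    goa: Sequence[GeneGoAnnotation],
    go: Ontology,
    match: str = "ancestor",
) -> RecoveryReport:
    """Score predicted GO terms against curated annotations, per aspect.

    ``predicted`` maps gene -> predicted GO terms (optionally with supporting
    genotype ids).  Duplicate GOA lines are deduplicated before counting.
    With ``match="ancestor"`` (default) a prediction p recovers an annotation
    t when p == t or either is an ancestor of the other in the is_a ∪ part_of
    closure; ``match="exact"`` requires identity.  Genes that appear in the
    GOA with no predictions count toward the totals and are never recovered.
    """
    if match not in ("ancestor", "exact"):
        raise ValueError(f"unknown match rule {match!r}")
    axioms = AxiomSet.from_ontology(go)
    preds = _normalize_predictions(predicted)

    def related(p: str, t: str) -> bool:
        if p == t:
            return True
        if match == "exact":
            return False
        return p in axioms.ispart_ancestors(t) or t in axioms.ispart_ancestors(p)

    unique = sorted({(a.gene_id, a.go_id, a.aspect) for a in goa})
    recovered: dict[str, int] = {a: 0 for a in ASPECTS}
    totals: dict[str, int] = {a: 0 for a in ASPECTS}
    recovering_terms: dict[str, set[str]] = defaultdict(set)
    for gene, go_id, aspect in unique:
        totals[aspect] += 1
        hits = [p for p in preds.get(gene, ()) if related(p, go_id)]
        if hits:
            recovered[aspect] += 1
            recovering_terms[gene].update(hits)

    candidates = []
    for gene in sorted(preds):
        for term in sorted(preds[gene]):
            if term not in recovering_terms[gene]:
                candidates.append(
                    NovelCandidate(gene, term, tuple(preds[gene][term]))
                )
    return RecoveryReport(
        aspects={a: AspectCounts(recovered[a], totals[a]) for a in ASPECTS},
        novel_candidates=candidates,
    )


# ---------------------------------------------------------------------------
# Report serialization
# ---------------------------------------------------------------------------


def write_report(report: RecoveryReport) -> str:
    """TSV: one ``aspect`` row per GO aspect (percentage to one decimal, NA
    when the aspect is empty), then one ``candidate`` row per novel candidate,
    deterministically ordered."""
    lines = ["kind\taspect_or_gene\trecovered_or_go\ttotal_or_genotypes\tpercentage"]
    for aspect in ASPECTS:
        counts = report.aspects.get(aspect, AspectCounts())
        pct = counts.percentage
        rendered = "NA" if pct is None else f"{pct:.1f}"
        lines.append(f"aspect\t{aspect}\t{counts.recovered}\t{counts.total}\t{rendered}")
    for cand in sorted(report.novel_candidates, key=lambda c: (c.gene_id, c.go_id)):
        genotypes = ",".join(cand.genotype_ids)
        lines.append(f"candidate\t{cand.gene_id}\t{cand.go_id}\t{genotypes}\t")
    return "\n".join(lines) + "\n"


def read_report(text: str) -> RecoveryReport:
    """Inverse of :func:`write_report` (percentages are recomputed)."""
    report = RecoveryReport()
    for line in text.splitlines()[1:]:
        if not line.strip():
            continue
        kind, a, b, c, _ = line.split("\t")
        if kind == "aspect":
            report.aspects[a] = AspectCounts(int(b), int(c))
        elif kind == "candidate":
            genotypes = tuple(c.split(",")) if c else ()
            report.novel_candidates.append(NovelCandidate(a, b, genotypes))
        else:
            raise ValueError(f"unknown report row kind {kind!r}")
    return report
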