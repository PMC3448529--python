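"""Deterministic mini-ontologies and synthetic benchmarks.

The four mini-ontologies are hand-curated, desk-scale slices of GO, PATO,
ChEBI and APO containing every identifier the worked examples use, with is_a
and part_of edges mirroring the public ontologies' structure among those
terms.  They are frozen constants: no network fetch, byte-identical builds.

Deliberate fixture choices (the mini-ontologies approximate, they do not
reproduce, the public releases):

* GO:0044237 (cellular metabolic process) reaches GO:0009987 (cellular
  process) through a ``part_of`` edge here, exercising the part-of path
  semantics of the reasoner, where public GO asserts plain ``is_a``;
* PATO:0000462 (absent) sits under PATO:0000460 (abnormal), so that
  absence-qualified phenotypes classify under abnormality-defined classes;
* APO branch-root ids, the id APO:0000003 for the *decreased* qualifier and
  the APO:00009xx observables (kinase activity, G1 phase progression,
  autophagy) are synthetic — the public APO ids for these are not fixed by
  the worked examples.  All other CURIEs are the public ones.

``simulate_benchmark`` generates a phenotype table and a gene-GO table with a
*planted* per-annotation recovery probability and records the realized ground
truth, so the pipeline's measured recovery can be checked against an
independently known answer.
"""
from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .eq_core import (
    And,
    Atom,
    ClassExpression,
    EqphenError,
    HAS_PART,
    HAS_QUALITY,
    PART_OF,
    PHENOTYPE_OF,
    Some,
)
from .obo_io import (
    IntersectionDefinition,
    Ontology,
    OntologyTerm,
    merge_ontologies,
    write_obo,
)

__all__ = [
    "FixtureCatalog",
    "SyntheticBenchmark",
    "build_mini_ontologies",
    "simulate_benchmark",
    "sample_phenotype_table",
    "cln3_scenario",
    "build_cross_species_demo",
    "random_expression",
    "UNION_DEFINITIONS",
    "PHENOTYPE_HEADER",
    "GOA_HEADER",
]

PHENOTYPE_HEADER = "genotype_id\tgene_id\tobservable_id\tqualifier_id\tchemical_id\tcondition"
GOA_HEADER = "gene_id\tgo_id\taspect"

#: Union-defined classes (not expressible as an OBO intersection_of):
#: term -> (quality, bearers).  Metabolism-and-growth is a phenotype of
#: either cellular metabolic process or cellular growth.
UNION_DEFINITIONS: dict[str, tuple[str, tuple[str, ...]]] = {
    "APO:0000094": ("PATO:0000001", ("GO:0044237", "GO:0016049")),
}

# (id, name, namespace, is_a parents, part_of parents)
_GO_TERMS = [
    ("GO:0008150", "biological_process", "biological_process", [], []),
    ("GO:0009987", "cellular process", "biological_process", ["GO:0008150"], []),
    ("GO:0008152", "metabolic process", "biological_process", ["GO:0008150"], []),
    ("GO:0050896", "response to stimulus", "biological_process", ["GO:0008150"], []),
    ("GO:0040011", "locomotion", "biological_process", ["GO:0008150"], []),
    ("GO:0023052", "signaling", "biological_process", ["GO:0008150"], []),
    ("GO:0000003", "reproduction", "biological_process", ["GO:0008150"], []),
    ("GO:0002376", "immune system process", "biological_process", ["GO:0008150"], []),
    ("GO:0048869", "cellular developmental process", "biological_process", ["GO:0009987"], []),
    ("GO:0030154", "cell differentiation", "biological_process", ["GO:0048869"], []),
    # part_of edge: see module docstring
    ("GO:0044237", "cellular metabolic process", "biological_process", ["GO:0008152"], ["GO:0009987"]),
    ("GO:0006914", "autophagy", "biological_process", ["GO:0044237"], []),
    ("GO:0016049", "cell growth", "biological_process", ["GO:0009987"], []),
    ("GO:0007049", "cell cycle", "biological_process", ["GO:0009987"], []),
    ("GO:0022402", "cell cycle process", "biological_process", ["GO:0009987"], ["GO:0007049"]),
    ("GO:1903047", "mitotic cell cycle process", "biological_process", ["GO:0022402"], []),
    ("GO:0000278", "mitotic cell cycle", "biological_process", ["GO:0007049"], []),
    ("GO:0000080", "G1 phase of mitotic cell cycle", "biological_process", [], ["GO:0000278"]),
    ("GO:0031576", "G2/M transition checkpoint", "biological_process", [], ["GO:0007049"]),
    ("GO:0007114", "cell budding", "biological_process", ["GO:0009987"], []),
    ("GO:0009408", "response to heat", "biological_process", ["GO:0050896"], []),
    ("GO:0034605", "cellular response to heat", "biological_process", ["GO:0009408"], []),
    ("GO:0042221", "response to chemical stimulus", "biological_process", ["GO:0050896"], []),
    ("GO:0010038", "response to metal ion", "biological_process", ["GO:0042221"], []),
    ("GO:0005575", "cellular_component", "cellular_component", [], []),
    ("GO:0005623", "cell", "cellular_component", ["GO:0005575"], []),
    ("GO:0005618", "cell wall", "cellular_component", ["GO:0005575"], []),
    ("GO:0009277", "fungal-type cell wall", "cellular_component", ["GO:0005618"], []),
    ("GO:0005739", "mitochondrion", "cellular_component", ["GO:0005575"], []),
    ("GO:0005634", "nucleus", "cellular_component", ["GO:0005575"], []),
    ("GO:0003674", "molecular_function", "molecular_function", [], []),
    ("GO:0016740", "transferase activity", "molecular_function", ["GO:0003674"], []),
    ("GO:0016301", "kinase activity", "molecular_function", ["GO:0016740"], []),
    ("GO:0004674", "protein serine/threonine kinase activity", "molecular_function", ["GO:0016301"], []),
    ("GO:0003700", "DNA-binding transcription factor activity", "molecular_function", ["GO:0003674"], []),
]

_PATO_TERMS = [
    ("PATO:0000001", "quality", "quality", [], []),
    ("PATO:0001236", "process quality", "quality", ["PATO:0000001"], []),
    ("PATO:0001241", "physical object quality", "quality", ["PATO:0000001"], []),
    ("PATO:0000051", "morphology", "quality", ["PATO:0001241"], []),
    ("PATO:0000052", "shape", "quality", ["PATO:0000051"], []),
    ("PATO:0000117", "size", "quality", ["PATO:0001241"], []),
    ("PATO:0000460", "abnormal", "quality", ["PATO:0000001"], []),
    ("PATO:0000461", "normal", "quality", ["PATO:0000001"], []),
    ("PATO:0000462", "absent", "quality", ["PATO:0000460"], []),
    ("PATO:0000502", "delayed", "quality", ["PATO:0001236"], []),
    ("PATO:0000297", "arrested", "quality", ["PATO:0001236"], []),
    ("PATO:0001457", "sensitivity of a process", "quality", ["PATO:0001236"], []),
    ("PATO:0001551", "increased sensitivity of a process", "quality", ["PATO:0001457"], []),
]

_CHEBI_TERMS = [
    ("CHEBI:24431", "chemical entity", "chebi_ontology", [], []),
    ("CHEBI:37577", "chemical compound", "chebi_ontology", ["CHEBI:24431"], []),
    ("CHEBI:26710", "sodium chloride", "chebi_ontology", ["CHEBI:37577"], []),
]

# The four top-level hierarchies: observable, qualifier, experiment type,
# mutant type.  EQ definitions attach only under observable; qualifiers map
# to PATO via the qualifier table, not via intersection_of.
_APO_ROOTS = [
    ("APO:0000017", "observable", "observable"),
    ("APO:0000203", "qualifier", "qualifier"),
    ("APO:0000019", "experiment type", "experiment_type"),
    ("APO:0000020", "mutant type", "mutant_type"),
]

# (id, name, EQ definition as (quality, bearer, during, towards) or None)
_APO_OBSERVABLES = [
    ("APO:0000051", "cell shape", ("PATO:0000052", "GO:0005623", None, None)),
    ("APO:0000053", "cell wall morphology", ("PATO:0000051", "GO:0005618", None, None)),
    ("APO:0000142", "critical cell size at G2/M", ("PATO:0000117", "GO:0005623", "GO:0031576", None)),
    ("APO:0000066", "cellular process", ("PATO:0000001", "GO:0009987", None, None)),
    ("APO:0000023", "development", ("PATO:0000001", "GO:0048869", None, None)),
    ("APO:0000094", "metabolism and growth", None),  # union, see UNION_DEFINITIONS
    ("APO:0000090", "metal resistant", ("PATO:0001457", "GO:0010038", None, None)),
    ("APO:0000087", "resistance to chemicals", ("PATO:0001457", "GO:0042221", None, "CHEBI:37577")),
    ("APO:0000147", "heat sensitivity", ("PATO:0001457", "GO:0009408", None, None)),
    ("APO:0000024", "budding", ("PATO:0000001", "GO:0007114", None, None)),
    ("APO:0000253", "cell cycle progression", ("PATO:0000001", "GO:0022402", None, None)),
    # synthetic observables (benchmark / demo coverage)
    ("APO:0000901", "kinase activity phenotype", ("PATO:0000001", "GO:0016301", None, None)),
    ("APO:0000902", "G1 phase progression", ("PATO:0000001", "GO:0000080", None, None)),
    ("APO:0000903", "autophagy", ("PATO:0000001", "GO:0006914", None, None)),
]

_APO_QUALIFIERS = [
    ("APO:0000002", "abnormal"),
    ("APO:0000003", "decreased"),
    ("APO:0000004", "increased"),
    ("APO:0000005", "absent"),
    ("APO:0000250", "arrested"),
]


def _term(
    curie: str,
    name: str,
    namespace: str,
    is_a: Sequence[str] = (),
    part_of: Sequence[str] = (),
    eq: Optional[tuple] = None,
) -> OntologyTerm:
    intersection = None
    if eq is not None:
        quality, bearer, during, towards = eq
        differentia = [("inheres_in", bearer)]
        if during:
            differentia.append(("during", during))
        if towards:
            differentia.append(("towards", towards))
        intersection = IntersectionDefinition(quality, tuple(differentia))
    return OntologyTerm(
        id=curie,
        name=name,
        namespace=namespace,
        is_a=list(is_a),
        relationships=[("part_of", p) for p in part_of],
        intersection_of=intersection,
    )


def _ontology(rows) -> Ontology:
    ont = Ontology()
    for curie, name, namespace, is_a, part_of in rows:
        ont.terms[curie] = _term(curie, name, namespace, is_a, part_of)
    return ont


@dataclass
class FixtureCatalog:
    mini_go: Ontology
    mini_pato: Ontology
    mini_chebi: Ontology
    mini_apo: Ontology
    union_definitions: dict[str, tuple[str, tuple[str, ...]]] = field(
        default_factory=lambda: dict(UNION_DEFINITIONS)
    )

    def merged(self) -> Ontology:
        return merge_ontologies(
            [self.mini_go, self.mini_pato, self.mini_chebi, self.mini_apo]
        )

    def obo_documents(self) -> dict[str, str]:
        """Serialized OBO text per ontology, keyed by file stem."""
        return {
            "mini-go": write_obo(self.mini_go),
            "mini-pato": write_obo(self.mini_pato),
            "mini-chebi": write_obo(self.mini_chebi),
            "mini-apo": write_obo(self.mini_apo),
        }

    def union_table(self) -> str:
        lines = ["# term_id\tquality_id\tbearers (|-separated)"]
        for term_id in sorted(self.union_definitions):
            quality, bearers = self.union_definitions[term_id]
            lines.append(f"{term_id}\t{quality}\t{'|'.join(bearers)}")
        return "\n".join(lines) + "\n"


def build_mini_ontologies() -> FixtureCatalog:
    """Build the four mini-ontologies; deterministic (two builds are equal,
    and serialize byte-identically)."""
    apo = Ontology()
    for curie, name, namespace in _APO_ROOTS:
        apo.terms[curie] = _term(curie, name, namespace)
    for curie, name, eq in _APO_OBSERVABLES:
        apo.terms[curie] = _term(curie, name, "observable", is_a=["APO:0000017"], eq=eq)
    for curie, name in _APO_QUALIFIERS:
        apo.terms[curie] = _term(curie, name, "qualifier", is_a=["APO:0000203"])
    apo.terms["APO:0000301"] = _term(
        "APO:0000301", "classical genetics", "experiment_type", is_a=["APO:0000019"]
    )
    apo.terms["APO:0000302"] = _term(
        "APO:0000302", "null mutant", "mutant_type", is_a=["APO:0000020"]
    )
    return FixtureCatalog(
        mini_go=_ontology(_GO_TERMS),
        mini_pato=_ontology(_PATO_TERMS),
        mini_chebi=_ontology(_CHEBI_TERMS),
        mini_apo=apo,
    )


def build_cross_species_demo() -> Ontology:
    """A two-term cross-species phenotype mini-ontology with EQ-defined
    classes (abnormal autophagy; abnormal metabolism), for classification of
    yeast expressions under another species' ontology."""
    ont = Ontology()
    ont.terms["XPO:0000001"] = _term(
        "XPO:0000001", "abnormal autophagy", "cross_species_phenotype",
        eq=("PATO:0000460", "GO:0006914", None, None),
    )
    ont.terms["XPO:0000002"] = _term(
        "XPO:0000002", "abnormal metabolism", "cross_species_phenotype",
        eq=("PATO:0000460", "GO:0008152", None, None),
    )
    return ont


# ---------------------------------------------------------------------------
# Worked-example tables
# ---------------------------------------------------------------------------


def sample_phenotype_table() -> str:
    """The worked-example annotation records: genotype S000029075 (three
    observable/qualifier pairs) and S000000649 (a chemical triple)."""
    rows = [
        PHENOTYPE_HEADER,
        "S000029075\tCDC29\tAPO:0000147\tAPO:0000004\t\t",
        "S000029075\tCDC29\tAPO:0000024\tAPO:0000005\t\t",
        "S000029075\tCDC29\tAPO:0000253\tAPO:0000250\t\t",
        "S000000649\tGENE0649\tAPO:0000087\tAPO:0000003\tCHEBI:26710\t",
    ]
    return "\n".join(rows) + "\n"


def cln3_scenario() -> tuple[str, str]:
    """(phenotype table, gene-GO table) for the novel-candidate scenario: the
    CLN3 genotype carries a G1-phase-progression phenotype whose extracted
    GO term (GO:0000080) is absent from, and unrelated to, CLN3's curated
    annotations — so it must surface as a novel candidate."""
    phenotypes = "\n".join(
        [
            PHENOTYPE_HEADER,
            "S000CLN3\tCLN3\tAPO:0000902\tAPO:0000002\t\t",
        ]
    ) + "\n"
    goa = "\n".join([GOA_HEADER, "CLN3\tGO:0016301\tF"]) + "\n"
    return phenotypes, goa


# ---------------------------------------------------------------------------
# Synthetic recovery benchmark
# ---------------------------------------------------------------------------

# Per-observable plant tables.  "related" terms are ancestor/descendant of
# the observable's extracted GO set by construction; each observable's
# "unrelated" background term is unrelated to *every* term any benchmark
# observable can predict.  Related pools are pairwise disjoint across
# observables and background terms are unique per observable, so no two
# draws for a gene ever collide on (gene, term, aspect) — deduplication in
# the comparator removes nothing and realized recovery stays an unbiased
# binomial draw at the planted rate.
_BENCH_OBSERVABLES = [
    # (observable, aspect of its GOA draw, related pool, unrelated background)
    ("APO:0000253", "P", ("GO:0022402", "GO:0007049", "GO:1903047"), "GO:0040011"),
    ("APO:0000147", "P", ("GO:0009408", "GO:0034605", "GO:0050896"), "GO:0023052"),
    ("APO:0000023", "P", ("GO:0048869", "GO:0030154"), "GO:0000003"),
    ("APO:0000090", "P", ("GO:0010038", "GO:0042221"), "GO:0002376"),
    ("APO:0000053", "C", ("GO:0005618", "GO:0009277"), "GO:0005739"),
    ("APO:0000142", "C", ("GO:0005623", "GO:0005575"), "GO:0005634"),
    ("APO:0000901", "F", ("GO:0016301", "GO:0016740", "GO:0004674"), "GO:0003700"),
]
_BENCH_QUALIFIER = "APO:0000002"  # abnormal: plain substitution


@dataclass
class SyntheticBenchmark:
    """A generated benchmark with its recorded ground truth.

    ``expected_recovered``/``expected_total`` count unique (gene, term,
    aspect) GOA entries after deduplication, exactly as the comparator does;
    a planted-recoverable entry is recoverable by construction and a planted
    background entry is unrelated to every predicted term by construction, so
    pipeline recovery must equal the realized truth exactly.
    """

    n_genes: int
    planted_rate: float
    seed: int
    phenotype_table: str
    goa_table: str
    expected_recovered: dict[str, int]
    expected_total: dict[str, int]

    def expected_percentage(self, aspect: str) -> Optional[float]:
        total = self.expected_total.get(aspect, 0)
        if total == 0:
            return None
        return 100.0 * self.expected_recovered[aspect] / total


def simulate_benchmark(
    n_genes: int, planted_rate: float, seed: int
) -> SyntheticBenchmark:
    """Generate phenotype + GOA tables with a planted recovery probability.

    For each gene, one to three observables are drawn; each contributes one
    GOA annotation which, with probability ``planted_rate``, is drawn from
    terms related to the observable's extracted GO set (self, ancestor or
    descendant) and otherwise from an unrelated background term of the same
    aspect.  The realized recoverable counts are recorded as ground truth.
    Same seed, same bytes.
    """
    if not 0.0 <= planted_rate <= 1.0:
        raise EqphenError(f"planted_rate must be in [0, 1], got {planted_rate}")
    if n_genes < 1:
        raise EqphenError(f"n_genes must be >= 1, got {n_genes}")
    rng = random.Random(seed)
    phen_rows = [PHENOTYPE_HEADER]
    goa_rows = [GOA_HEADER]
    truth: dict[tuple[str, str, str], bool] = {}
    for i in range(1, n_genes + 1):
        gene = f"GENE{i:05d}"
        genotype = f"S9{i:06d}"
        k = rng.randint(1, 3)
        chosen = rng.sample(_BENCH_OBSERVABLES, k)
        for observable, aspect, related, background in chosen:
            phen_rows.append(
                f"{genotype}\t{gene}\t{observable}\t{_BENCH_QUALIFIER}\t\t"
            )
            if rng.random() < planted_rate:
                term, recoverable = rng.choice(related), True
            else:
                term, recoverable = background, False
            goa_rows.append(f"{gene}\t{term}\t{aspect}")
            truth[(gene, term, aspect)] = recoverable
    expected_recovered = {a: 0 for a in ("P", "F", "C")}
    expected_total = {a: 0 for a in ("P", "F", "C")}
    for (_, _, aspect), recoverable in truth.items():
        expected_total[aspect] += 1
        if recoverable:
            expected_recovered[aspect] += 1
    return SyntheticBenchmark(
        n_genes=n_genes,
        planted_rate=planted_rate,
        seed=seed,
        phenotype_table="\n".join(phen_rows) + "\n",
        goa_table="\n".join(goa_rows) + "\n",
        expected_recovered=expected_recovered,
        expected_total=expected_total,
    )


# ---------------------------------------------------------------------------
# Seeded random expressions (reasoner/grammar property testing)
# ---------------------------------------------------------------------------

_DEFAULT_ATOMS = ("GO:0009987", "GO:0007049", "GO:0022402", "GO:0005618")
_DEFAULT_RELATIONS = (PHENOTYPE_OF, HAS_PART, PART_OF, HAS_QUALITY)


def random_expression(
    rng: random.Random,
    atoms: Sequence[str] = _DEFAULT_ATOMS,
    relations: Sequence[str] = _DEFAULT_RELATIONS,
    max_depth: int = 3,
) -> ClassExpression:
    """A small random expression (<= ``max_depth`` nesting, conjunctions of
    2-3 operands) over the given atom and relation pools."""
    roll = rng.random()
    if max_depth <= 0 or roll < 0.4:
        return Atom(rng.choice(atoms))
    if roll < 0.75:
        return Some(
            rng.choice(relations),
            random_expression(rng, atoms, relations, max_depth - 1),
        )
    n = rng.randint(2, 3)
    return And(
        random_expression(rng, atoms, relations, max_depth - 1) for _ in range(n)
    )
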