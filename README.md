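# eqphen

Entity–quality (EQ) formalization and structural reasoning for yeast
phenotype annotations.

Yeast databases record phenotypes as pairs of ontology classes — an
*observable* (the affected trait, e.g. heat sensitivity) and a *qualifier*
(its comparative value, e.g. increased) — optionally extended by a chemical
to a triple. These pre-composed classes are opaque to cross-ontology
analysis. `eqphen` decomposes them: each observable carries an EQ definition
(a PATO quality Q inhering in a bearer entity E from GO or ChEBI, with
optional temporal and relational differentia), recorded in OBO flat files as
`intersection_of` clauses, and the package compiles those definitions — and
whole genotype–phenotype annotations — into composed class expressions such
as

```
phenotype-of some (has-part some (GO:0005618 and has-quality some PATO:0000051))
```

(a cell-wall-morphology phenotype: something that has a cell wall as part in
which a morphology quality inheres). Five phene patterns cover morphology,
stage-restricted traits (`during`), process phenotypes (with a reflexive,
transitive `part-of` step that imports GO's parthood structure),
dispositions, and relational qualities (`towards` a chemical). Qualifiers
compose either by quality substitution (arrested → PATO:0000297) or as
magnitude comparisons against *normal*
(`Q and increased-in-magnitude-relative-to some PATO:0000461`).

On top of the expressions sits a structural subsumption reasoner for the
conjunctive-existential fragment (description-tree homomorphism with the
property rules: `part-of` transitive + reflexive, the chain
`has-part ∘ part-of → has-part`), used to classify formalized annotations
under any EQ-defined ontology's classes, to infer a restructured observable
taxonomy, and to check qualifier/bearer consistency (process qualities may
not inhere in objects, and vice versa). Finally, a gene-function recovery
analysis extracts the GO classes from a gene's formalized phenotypes and
compares them, per GO aspect, against the gene's curated GO annotations;
predictions recovering nothing become novel candidate annotations.

For whom: curators and ontology engineers working with observable/qualifier
phenotype data who want logical definitions, cross-species classification,
and phenotype-derived function candidates without a full OWL toolchain.

## Expression grammar

```
expr     := conjunct ("and" conjunct)*
conjunct := CURIE | RELATION "some" filler | "(" expr ")"
filler   := CURIE | "(" expr ")"
RELATION := phenotype-of | has-part | part-of | has-quality | during
          | towards | increased-in-magnitude-relative-to
          | decreased-in-magnitude-relative-to
```

The bare token `normal` is accepted on input as an alias for PATO:0000461.

## Worked example

```
$ eqphen fixtures --out-dir demo
$ eqphen annotate --obo demo/mini-apo.obo --obo demo/mini-go.obo \
    --obo demo/mini-pato.obo --obo demo/mini-chebi.obo \
    --phenotypes demo/phenotypes.tsv
S000029075	phenotype	phenotype-of some (has-part some (GO:0009408 and has-quality some (PATO:0001457 and increased-in-magnitude-relative-to some PATO:0000461)))
S000029075	phenotype	phenotype-of some (has-part some (part-of some GO:0007114 and has-quality some PATO:0000462))
S000029075	phenotype	phenotype-of some (has-part some (GO:0022402 and has-quality some PATO:0000297))
S000000649	phenotype	phenotype-of some (has-part some (GO:0042221 and has-quality some (PATO:0001457 and towards some CHEBI:26710 and decreased-in-magnitude-relative-to some PATO:0000461)))
S000029075	combined	...
```

Genotype S000029075 (a conditional cell-division-cycle mutant) carries three
annotations — heat sensitivity: increased, budding: absent, cell cycle
progression: arrested — which become three expressions (increased composes
as a magnitude comparison, absent and arrested as quality substitutions) and
one combined class intersection for the genotype. S000000649's triple
(ionic stress resistance: decreased, sodium chloride) attaches the chemical
via `towards`.

```
$ eqphen infer-hierarchy --obo demo/mini-apo.obo --obo demo/mini-go.obo \
    --obo demo/mini-pato.obo --obo demo/mini-chebi.obo --unions demo/unions.tsv
APO:0000023	APO:0000066
APO:0000024	APO:0000066
APO:0000094	APO:0000066
APO:0000253	APO:0000066
APO:0000902	APO:0000066
APO:0000903	APO:0000094
```

The definitions alone restructure the observable taxonomy: *development*
(APO:0000023) and *metabolism and growth* (APO:0000094) — the latter defined
as a phenotype of *either* cellular metabolic process *or* cellular growth,
encoded as two sufficient conditions — are inferred to be kinds of *cellular
process* phenotype (APO:0000066) through GO's classification of processes.

```
$ eqphen recover --obo ... --phenotypes demo/benchmark-phenotypes.tsv \
    --goa demo/benchmark-goa.tsv --match ancestor
kind	aspect_or_gene	recovered_or_go	total_or_genotypes	percentage
aspect	P	111	222	50.0
aspect	F	29	55	52.7
aspect	C	61	115	53.0
...
```

Each `aspect` row gives recovered/total curated annotations per GO aspect
(the benchmark above plants a 50% recovery rate); `candidate` rows list
phenotype-derived GO terms that match none of the gene's curated
annotations — novel function candidates, such as CLN3's phenotype-derived
involvement in the G1 phase of the mitotic cell cycle (GO:0000080).

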