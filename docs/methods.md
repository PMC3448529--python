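# Methods

## The model

A phenotype is decomposed into an *entity* E that is affected and a
*quality* Q (from PATO) that describes how it is affected, with two optional
differentia: a temporal stage (the phenotype manifests `during` a process)
and a second entity (`towards`, the other argument of a relational quality
such as a sensitivity). These EQ definitions are stored in OBO 1.2
`intersection_of` blocks (genus = quality; `inheres_in` = bearer) and
compiled into class expressions over a fixed relation vocabulary. The
compiled form deliberately relates the organism to both objects and
processes through `has-part` rather than distinguishing `participates-in`,
`has-disposition` or `has-function`: drawing those distinctions against
current process/function ontologies produces wide-scale unsatisfiability,
so dispositional phenotypes use the same structural shape as object
phenotypes.

Five patterns, selected per observable:

| category | expression shape |
|---|---|
| object-morphology | `phenotype-of some (has-part some (E and has-quality some Q))` |
| temporal-object | object shape with `and during some S` in the bearer conjunction |
| process | `phenotype-of some (has-part some (part-of some E and has-quality some Q))` |
| disposition | object shape over a process bearer |
| relational | object shape with `Q and towards some C` as the quality |

Category is decided by, in order: a per-term override table; presence of
`towards` (relational); presence of `during` (temporal-object); quality
under *sensitivity of a process* PATO:0001457 (disposition); bearer in a
process/function namespace (process); otherwise object-morphology. The
`part-of` step in the process pattern is what imports the entity ontology's
parthood structure into the phenotype hierarchy; because `part-of` is
reflexive, expressions built without the step (the disposition shape) still
classify under process-pattern classes, so the two shapes interoperate.
The shipped override table routes *cell cycle progression* through the
simple bearer shape, matching the form its published annotation expression
uses.

A class defined as a phenotype of *either* of several bearers (metabolism
and growth) cannot be an OBO intersection; it is encoded as one
process-pattern expression per disjunct, registered as sufficient
conditions. For hierarchy placement the disjunct set is treated as
exhaustive (the class is below a parent iff every disjunct is), which is the
union reading of "a phenotype of either".

## Qualifier composition

Qualifiers compose in two ways, configured in `data/qualifiers.tsv`:

* **substitution** — the qualifier has a PATO equivalent (arrested →
  PATO:0000297, abnormal → PATO:0000460, absent → PATO:0000462). When the
  equivalent is an `is_a` descendant of the definition quality it replaces
  it; otherwise (abnormal vs shape, incomparable qualities) the two are
  conjoined. Either way the qualified annotation stays subsumed by its bare
  observable — the design invariant the whole annotation pipeline is tested
  against. The absent mapping is a configurable choice; a dedicated
  process-absence pattern was considered and left out because no published
  expression fixes its form.
* **magnitude** — increased/decreased wrap the quality as
  `(Q and increased-in-magnitude-relative-to some PATO:0000461)`, mirroring
  PATO's own construction of *increased sensitivity of a process*. The bare
  token `normal` is given the resolvable home PATO:0000461 and treated as a
  class, so every atom in a compiled expression is a CURIE.

A triple annotation's chemical attaches as (or specializes the definition's)
`towards` filler. Default mode also applies the triple's magnitude
qualifier; verbatim mode drops it, reproducing the published
chemical-resistance expression, which ignores "decreased". Both readings
are emitted because the intended semantics of "decreased resistance"
(decreased quality vs changed process) is genuinely ambiguous; neither is
asserted as canonical. Verbatim mode likewise reproduces the one published
equivalence that omits `has-part` (resistance to chemicals); default mode
normalizes to the uniform `has-part` form so subsumption behaves uniformly.

## Reasoning

Subsumption is a description-tree homomorphism check in the
conjunctive-existential fragment: atoms match along the reflexive-transitive
`is_a` closure; `part-of` edges match along any interleaving of expression
`part-of` edges and ontology `is_a`/`part_of` edges, including the empty
chain (reflexive); `has-part` absorbs a trailing `part-of` chain; all other
relations need one same-relation edge; conjunctions need all operands
matched. Equivalence-defined atoms are unfolded first; definitional cycles
are authoring errors and abort with the cycle named. No general TBox
saturation is performed — every construct the patterns emit falls inside
this fragment, which keeps an independent brute-force oracle feasible: the
test suite re-decides subsumption by *saturating* the specific tree
(materialized reflexive loops, transitive compositions, chain edges,
ontology part-of leaves, `is_a`-closed atom sets) followed by naive
matching, and the two implementations are compared on thousands of seeded
random instances.

Classification returns all defined subsumers and the most specific ones
(all minimal elements, sorted by CURIE — ties are kept, not broken).
Hierarchy inference runs pairwise class subsumption, strict edges only
(mutually subsuming classes produce no edge), transitive-reduces, and
reports edges absent from the asserted taxonomy. Completeness against a
full OWL reasoner is not claimed; the fragment reproduces the expected
restructuring of the observable taxonomy and is checked against the
pairwise oracle.

The qualifier consistency check uses PATO's top-level split (process quality
PATO:0001236 vs physical object quality PATO:0001241) against the bearer's
namespace; qualities under neither branch skip the check with a warning
rather than guessing.

## Fixtures and the synthetic benchmark

The four mini-ontologies are hand-curated constants (~55 terms total)
containing every identifier the worked examples use, with `is_a`/`part_of`
edges mirroring the public ontologies among those terms; they are closed
under reference and versioned in the repository, never fetched. Deliberate
deviations, chosen to exercise specific machinery, are flagged in the
`fixtures` module docstring: one `part_of` edge where public GO asserts
`is_a` (so the part-of path semantics is exercised by a real inference),
*absent* placed under *abnormal* (so absence-qualified phenotypes classify
under abnormality-defined cross-species classes), and synthetic ids for the
APO branch roots, the *decreased* qualifier and three benchmark observables
whose public ids the worked examples do not fix.

The historical recovery percentages for the real yeast corpus depend on
unversioned 2011-era database releases and an unstated matching rule, so
they are reference points, not reproduction targets. What the package
validates instead is the *comparator*: `simulate_benchmark(n_genes,
planted_rate, seed)` draws one to three observables per gene and one curated
GO annotation per observable, recoverable with probability `planted_rate`
(drawn from terms related to the observable's extracted GO set by
construction) and otherwise drawn from a per-observable background term
unrelated to every term the benchmark can predict. Related pools are
pairwise disjoint and background terms unique, so no two draws collide
after deduplication and the realized recovery is an unbiased binomial draw
whose per-annotation truth the generator records. The pipeline's measured
recovery must equal that recorded truth *exactly* — plant and comparator are
computed by independent routes — and lie within the 99% binomial envelope
of the planted rate. Default conditions: 200 genes, planted rate 0.5
(convergence is additionally checked at 2,000 genes). What passing does
not show: real SGD/GO data have deeper hierarchies, evidence codes,
annotation bias and far larger term sets; the benchmark validates counting
and matching logic, not biological recall.

The recovery matching rule is ancestor/descendant over the `is_a` ∪
`part_of` closure (either direction), because phenotype bearers are
deliberately high-level classes and exact matching would be near-vacuous;
`--match exact` is exposed for comparison. Empty aspects report `NA` rather
than 0.0 to distinguish absence of data from failure to recover.

## Numerical and interface choices

* Conjunction order is semantically irrelevant; compiled expressions keep
  the pattern's operand order so renderings match the published listings
  token-for-token, and `canonicalize` (flatten + lexicographic sort,
  idempotent) provides the bit-stable form used for combination and
  round-trip testing. The genotype-level combination is the canonicalized
  intersection of the genotype's phenotype expressions.
* `write_obo` output is deterministic (terms sorted by CURIE, fixed clause
  order, genus first); unrecognized OBO tags pass through verbatim so a
  parse/write cycle is lossless. Dangling cross-references are recorded and
  logged, never fatal; duplicate ids and malformed genus blocks are hard
  errors.
* All randomness flows through a single integer seed per generator
  (`random.Random`); same seed, byte-identical fixtures. Problem sizes used
  by the shipped test suite and acceptance script — 2,000 reasoner oracle
  pairs, 1,000 grammar round-trip ASTs, 200-gene benchmark — were chosen as
  comfortable desk-scale corpora for the ~30-CURIE fixture world.
* The AST has no union node (the one union lives in the compiler's
  sufficient conditions) and no negation, cardinality or universal
  restrictions; condition text on annotations is carried, never interpreted.

## Known limitations

Translation into external species' phenotype ontologies works only to the
extent bridging EQ definitions are loaded (demonstrated on a two-class
fixture ontology); experiment-type and mutant-type branches are carried in
fixtures but not formalized; the six-column annotation dialect is this
package's canonical format — a converter from live database exports is
future work.
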