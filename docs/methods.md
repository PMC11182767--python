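# Methods

## The graph model and its assumptions

The toolkit models knowledge as a directed property multigraph. A node is an
entity occurrence — a microbe name, a phenotype, an experiment group — typed
by one of the ontology's *detail types*. An edge is one sourced assertion: a
relation label plus a provenance identifier (a PMID for literature-derived
triples, a database name for mapped ones) and an attribute map holding
per-assertion evidence (case/control condition, P-value, mean relative
abundances).

Two identity rules drive everything else:

* **Node identity is name-based.** The key is `(normalized name, entity
  type)`, where normalization trims, collapses internal whitespace, unifies
  hyphen/en-dash variants and compares case-insensitively (display keeps the
  first-seen spelling). Source material spells the same taxon both
  "Escherichia-Shigella" and "Escherichia–Shigella"; without dash and case
  unification those would be distinct nodes and cross-source queries would
  silently miss evidence. No taxonomy resolution is attempted: the mention
  string *is* the node, which matches how the three sources are keyed and
  keeps merging transparent.
* **Edge identity includes provenance and attributes.** The key is
  `(subject, relation, object, source, attributes)`. Re-adding an identical
  assertion is a no-op, but the same association reported by a second PMID,
  or by the same database under a different case/control condition, is new
  evidence and stays a separate edge. A consequence worth stating: merged
  triple counts are exactly additive whenever the per-base edge keys are
  disjoint, and evidence strength is readable as edge multiplicity.

Relations are a closed vocabulary grouped into six categories (`sameAs`,
`hasProperty`, `subClassOf`, `regulation`, `treatment_effect`,
`comparison`). Each label carries a polarity and a significance flag;
`significantly_`-prefixed labels and the four regulation labels
(`increase`, `decrease`, `upregulate`, `downregulate`) mark associations
reported at P < 0.05 in their source. Unknown labels fail lookups rather
than being guessed, and unknown labels or entity types in ingested records
land in a rejects report with their positions — silent dropping is treated
as a defect. Label matching is case-insensitive with spaces mapped to
underscores, because the source tables mix `Positively_correlated_with` and
`positively_correlated_with`. The `equal_to`/`similar` labels are stored as
ordinary edges; no identity inference or OWL-style reasoning is performed.

Entity-type aliases: annotation exports write underscored forms
(`Swine_Breed`); the schema normalizes by removing underscores to the
camel-case detail types. "FeedEfficiency" exists both as a class and as a
detail type; the detail type is the queryable node label.

## Ingestion

**Curated annotations** arrive either as JSON `Triple_list` records
(optionally wrapped with a PMID) or as an association table with columns
Taxonomy / PMID / MicrobiotaName / Relation / Phenotype. Each table row
emits the relation edge (source = PMID) plus one structural
`belong_to` edge per distinct (microbe, taxonomy) pair — repeated structural
facts are not evidence, so they are not multiplied. Rows whose Relation cell
is empty get `correlated_with` and a `relation_imputed` edge attribute; the
substitute label is a keyword argument, since the blank cells' intent is
ambiguous in the source material. Obviously truncated PMIDs (the table
contains bare "7" and "13") are kept verbatim: fidelity over repair.

**Literature mentions** are parsed from the PubTator plain-text format
(`PMID|t|`, `PMID|a|`, tab-separated annotation lines; offsets are 0-based
into title + `" "` + abstract). Species-type mentions become
`(mention, hasSource, PMID)` and `(mention, hasID, concept id)` triples,
deduplicated per (mention, PMID) and (mention, concept id). `hasID` points
at the annotation's taxonomy/MeSH identifier — that is what an ID relation
is for — with a `strict_literal` flag available that reproduces the
PMID-valued variant some pipelines describe. `hasSource`/`hasID` and their
object types (`PMID`, `ConceptID`) are schema extensions registered under
the `hasProperty` category, since the base ontology does not list them but
the mention reduction requires them.

**Structured databases** are adapted through declarative column maps (YAML
sidecars naming the source columns for microbe, taxonomy rank, condition,
P-value, …), so new exports are a config change, not a code change.
Association records emit `belong_to` / `correlated_with` / `located_in`
edges with the evidence attributes on the `correlated_with` edge — putting
them on edges rather than on the microbe node keeps each piece of evidence
attached to the assertion it supports and is the testable choice.
Phenotype/species filtering is a caller-side predicate, not hard-coded.
Metabolite (`produce`) and pathway (`involved_in`) tables emit one edge per
distinct pair.

## Querying

The matcher finds *homomorphic* embeddings of a small pattern graph (two
variables may bind one node), which is Cypher's default semantics; results
are distinct projected rows sorted lexicographically by bound node names,
with per-row provenance collected from the matched edges. The
implementation is a backtracking join over edge constraints, and the test
suite holds it equal to exhaustive enumeration over all variable
assignments on hundreds of seeded random graphs.

The canned cases are thin formulations on top of it: case 1 filters
FE-adjacent microbes by exact label or relation metadata (a microbe counts
once however many PMIDs assert it); case 2 follows `produce` and
`involved_in` with minimum-degree filters (metabolites with ≥ 2 producers,
pathways with ≥ 2 member metabolites, both parameters); case 3 selects
significant positive relations grouped per knowledge base; cases 4 and 5
walk additive → design → group → microbe and breed ← design ← group →
microbe. The group → microbe hop uses `influence`, with a `relaxed` mode
accepting any regulation/treatment-effect relation. Patterns emit
deterministic `MATCH … return` text (node labels, exact names and relation
labels only; metadata-filtered edges have no Cypher surface form and
raise), and parsing the emitted text reproduces the pattern.

## Exports

Cypher scripts (MERGE per node, MATCH + CREATE per edge, backtick-quoted
identifiers, escaped single-quoted strings), Neo4j bulk-import CSV
(`:ID,name,:LABEL` / `:START_ID,:END_ID,:TYPE,source` + one column per
attribute key, RFC-4180) and GraphML (via networkx, edge attributes
flattened under an `a_` prefix). All writers iterate in sorted key order,
so output is byte-deterministic, and import ∘ export is the identity on the
graph. One representational limit: empty-string attribute values are
indistinguishable from absent in CSV, so empty values are uniformly treated
as absent at triple construction.

## Origin classification and evaluation

Origin classification partitions a queried metabolite set against a
reference table of host/microbiota/food flags into host-only,
microbiota-only, shared and unclassified (absent, or present with neither
flag) — the four cells always cover the query set, and nothing is silently
dropped. The food flag is orthogonal to the partition and is reported as a
percentage rounded half-even to two decimals. The reference table is
user-supplied because origin databases are external and versioned; the
packaged table is a synthetic reconstruction matching the published totals
(16/19/15 with 3 left unclassified — the published partition covers only 50
of its 53 metabolites, and the remainder is modeled as unclassified; 27 of
53 feed-related, 50.94 %).

QA evaluation scores one question as one unit: a question is correct when
its returned answer set matches the expected set after name normalization
(exact set equality by default; a Jaccard-overlap mode with a threshold is
available). Recall = correct/expected, precision = correct/returned, F1 is
their harmonic mean. On the packaged 30-question benchmark (28 answered, 25
correct) this gives recall 83.3 %, precision 89.3 % and F1 0.862 — note
that 0.862 is what the harmonic-mean formula yields for these counts; any
larger figure quoted for the same counts is not reproducible from the
formula. The benchmark files are synthetic reconstructions at those counts.

## Synthetic data: what it emulates and what it does not

* `random_kb(n_nodes, n_triples, pool, seed)` produces exact-size graphs
  with unique per-edge provenance; entity types are a pure function of the
  node name so that two bases sharing pool names share node keys, making
  merge overlap controllable. The full-scale trio uses the real per-base
  sizes (2,307/6,217; 26,203/23,948; 14,297/28,731) with 260 node keys
  shared between the curated and mention bases, so the merged graph has
  42,547 nodes and 58,896 triples. These graphs exercise *arithmetic and
  determinism* — they have no biological structure, so passing merge tests
  says nothing about entity-resolution quality on real names beyond the
  normalization rules above.
* `synthetic_pubtator` produces format-exact documents whose annotation
  offsets provably slice the text to the mention; it does not emulate
  realistic abstracts or annotation noise beyond field-count corruption
  added in tests.
* The curated association fixture is a verbatim transcription of the
  source table (95 rows), keeping its spellings ("Colinsella",
  "Subdoligranulu") and truncated PMIDs; a corrected-names overlay ships
  separately and is never used by the headline checks. Rows with a blank
  microbe cell in the printed table are read as continuations of the
  previous microbe, the standard convention for such tables.

## Numerical and procedural choices

* Deterministic iteration everywhere (sorted node/edge keys); merge is
  associative and order-insensitive up to graph equality, with first-seen
  display names winning in argument order.
* Percentages use round-half-even to 2 decimals; F1 is reported unrounded
  and rounded to 3 decimals in the CLI.
* Generators take explicit seeds; the acceptance script threads its
  `--seed` into the synthetic trio.
* Degenerate inputs: empty graphs export header-only CSV; empty pattern
  projections default to all variables; empty QA answer sets count as
  unanswered; a graph with no feed-efficiency node yields empty query-1
  results rather than an error.

## Known limitations

* No taxonomy-aware entity resolution (synonyms, strain/species rollup);
  name normalization only.
* No inference: `sameAs`-category edges are not executed as identity, and
  there is no transitive closure over `belong_to`.
* The Cypher importer/exporter handle the toolkit's own dialect, not
  arbitrary Cypher; the pattern engine is not a Cypher executor (no WHERE
  expressions, paths of variable length, or aggregation).
* Full-scale per-base node/triple counts from raw sources require the
  original corpus and database snapshots; the toolkit reproduces the
  integration arithmetic on size-matched synthetic bases instead.
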