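# pgmkit

A toolkit for building, merging and querying an ontology-validated knowledge
graph of **pig gut microbiota and feed efficiency (FE)**.

Feed efficiency — how much weight a pig gains per unit of feed (feed
conversion ratio, residual feed intake) — is partly shaped by the gut
microbiota, but the evidence is scattered across curated literature,
automatic literature annotation services and structured association
databases. `pgmkit` integrates those three source shapes into one
provenance-preserving property graph and interrogates it with graph-pattern
queries:

* **curated annotations** (`pgmReading`): manually extracted
  (subject, relation, object) triples from publications, validated against a
  closed domain ontology of 11 entity classes (Swine, Microbiota,
  FeedEfficiency, Performance, Gene, Protein, Metabolism, Experiment, Feed,
  Disease, Environment) and six relation categories;
* **literature mentions** (`pgmPubtator`): PubTator-format files reduced to
  `(microbe, hasSource, PMID)` and `(microbe, hasID, taxonomy/MeSH id)`
  triples;
* **structured databases** (`pgmDatabase`): microbe–phenotype association
  tables (condition, P-value and relative abundances kept as edge
  attributes), microbe→metabolite tables and metabolite→pathway tables,
  adapted through declarative column maps.

## The graph model

A triple is `(subject, subject_type, relation, object, object_type)` plus a
provenance identifier (PMID or database name) and an attribute map, all
carried on the edge. Node identity is name-based — `(normalized name,
entity type)` — so the same microbe reported by two sources collapses to one
node, while edges are **never** deduplicated across provenance: merged
triple counts are exactly additive whenever edge keys are disjoint. Relation
labels carry a category (`sameAs`, `hasProperty`, `subClassOf`,
`regulation`, `treatment_effect`, `comparison`), a polarity
(positive/negative/neutral) and a significance flag (labels prefixed
`significantly_`, plus `increase`/`decrease`/`upregulate`/`downregulate`,
denote P < 0.05 associations).

Queries are homomorphic graph-pattern matches (Cypher's default semantics);
five canned cases cover FE-adjacent microbes, the microbe → metabolite →
pathway two-hop chain, significant positive factors, and the feed-additive
and pig-breed path queries. Graphs round-trip bit-exactly through Cypher
scripts, Neo4j bulk-import CSV and GraphML.

## Worked example

```python
import pgmkit as pk
from pgmkit import fixtures as fx

graph = fx.table2_graph()          # curated FE association table
print(graph)                       # PropertyGraph(name='pgmReading', nodes=70, triples=158)

pos = pk.q1_fe_microbes(graph, relation="Positively_correlated_with")
neg = pk.q1_fe_microbes(graph, relation="Negatively_correlated_with")
print(len(pos), len(neg))          # 25 16

qc = fx.querycase_graph()          # printed path triples for the complex cases
print(sorted(pk.q4_additive_path(qc, "fermented spent mushroom substrates")))
# ['Bacteroidetes', 'Clostridium disporicum', 'Firmicutes', 'Lactobacillus',
#  'Lactobacillus gasseri', 'Roseburia', 'Streptococcus']
print(sorted(pk.q5_breed_path(qc, "Duroc × Large White × Landrace")))
# ['Bacteroidetes', 'Firmicutes']
```

25 microbes are positively and 16 negatively correlated with feed efficiency
under exact relation labels; the additive query walks
additive → experiment design → experiment group → microbes and returns the
seven taxa affected by fermented spent mushroom substrates.

The same pipeline is scriptable from the shell:

```bash
pgmkit fixtures --out fixtures/
pgmkit ingest-reading fixtures/table2_fe_associations.tsv --table --out reading.graphml
pgmkit query reading.graphml --case 1 --relation Positively_correlated_with
pgmkit eval --expected fixtures/qa_synthetic_expected.json \
            --returned fixtures/qa_synthetic_returned.json
# n_expected  n_returned  n_correct  recall  precision  f1
# 30          28          25         0.833   0.893      0.862
```

## Layout

```
src/pgmkit/
  ontology.py    closed schema: classes, detail types, relation metadata
  graph.py       property multigraph, merge, stats
  io.py          Cypher / Neo4j-CSV / GraphML exporters and importers
  reading.py     curated-annotation and association-table ingestion
  pubtator.py    PubTator parsing and mention-triple extraction
  databases.py   association / metabolite / pathway table mapping
  query.py       pattern matcher, five query cases, Cypher emission
  origins.py     metabolite origin classification
  evaluation.py  QA recall / precision / F1 scoring
  fixtures.py    packaged tables and seeded random generators
  cli.py         `pgmkit` command-line interface
  data/          ontology, fixture tables, column maps
```

See `docs/methods.md` for the modelling decisions and known limitations.
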