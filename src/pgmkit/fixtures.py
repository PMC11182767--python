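"""Packaged fixtures and parameterized random generators.

Everything the toolkit needs for testing ships with the package or is
generated programmatically:

* the curated feed-efficiency association table (one row per literature
  assertion, with taxonomy, PMID and relation label);
* the query-case path fixture (feed additive → experiment design →
  experiment group → microbes; breed → designs → group → microbes);
* microbe→metabolite and metabolite→pathway tables;
* a synthetic metabolite origin-reference table (53 metabolites: 16
  host-only, 19 microbiota-only, 15 shared, 3 unclassified; 27 feed-related)
  and a synthetic 30-question QA benchmark (28 answered, 25 correct);
* seeded random knowledge bases and random PubTator files.

Generators are pure functions of their parameters and seed.
"""

from __future__ import annotations

import random
import shutil
from importlib import resources
from pathlib import Path

import pandas as pd

from .databases import map_metabolite_table, map_pathway_table, read_pair_table
from .graph import PropertyGraph, Triple
from .ontology import OntologySchema, default_schema
from .pubtator import PubtatorAnnotation, PubtatorDocument, serialize_pubtator
from .reading import load_fe_association_table, parse_annotation_export

__all__ = [
    "data_path",
    "table2_table",
    "table2_fixture",
    "table2_graph",
    "querycase_graph",
    "metabolite_graph",
    "origins_path",
    "qa_paths",
    "random_kb",
    "table1_trio",
    "TABLE1_SIZES",
    "TABLE1_SHARED_NODES",
    "synthetic_pubtator",
    "write_all",
]

_DATA_FILES = (
    "ontology.yaml",
    "table2_fe_associations.tsv",
    "corrected_names.tsv",
    "querycase_triples.json",
    "gutmgene_metabolites.tsv",
    "kegg_pathways.tsv",
    "origins_synthetic.tsv",
    "qa_synthetic_expected.json",
    "qa_synthetic_returned.json",
    "colmap_addagma.yaml",
    "colmap_gutmgene.yaml",
    "colmap_kegg.yaml",
)

#: knowledge-base sizes (nodes, triples) used for merge-scale tests
TABLE1_SIZES = {
    "pgmReading": (2307, 6217),
    "pgmPubtator": (26203, 23948),
    "pgmDatabase": (14297, 28731),
}
#: node keys shared between the curated and mention-derived bases
TABLE1_SHARED_NODES = 260


def data_path(name: str) -> Path:
    """Filesystem path of a packaged data file."""
    return Path(str(resources.files("pgmkit.data").joinpath(name)))


def table2_table(corrected_names: bool = False) -> pd.DataFrame:
    """The curated feed-efficiency association table as a DataFrame.

    Spellings are kept verbatim as printed in the source material (including
    e.g. "Colinsella" and "Subdoligranulu"); ``corrected_names=True`` applies
    the corrected-names overlay instead.
    """
    df = pd.read_csv(
        data_path("table2_fe_associations.tsv"), sep="\t", dtype=str, keep_default_na=False
    )
    if corrected_names:
        overlay = pd.read_csv(
            data_path("corrected_names.tsv"), sep="\t", dtype=str, keep_default_na=False
        )
        mapping = dict(zip(overlay["printed"], overlay["corrected"]))
        df["MicrobiotaName"] = df["MicrobiotaName"].map(lambda m: mapping.get(m, m))
    return df


def table2_graph(schema: OntologySchema | None = None) -> PropertyGraph:
    """The curated association table loaded into a property graph."""
    graph, _report = load_fe_association_table(table2_table(), schema=schema)
    return graph


def _expected_q1_sets(df: pd.DataFrame, schema: OntologySchema) -> dict[str, set[str]]:
    """Expected query-case-1 answer sets, derived by row scanning with the
    ontology's relation filters (independent of the graph machinery)."""
    from .ontology import canonical_relation

    exact_pos: set[str] = set()
    exact_neg: set[str] = set()
    significant_pos: set[str] = set()
    for _, row in df.iterrows():
        rel = str(row["Relation"]).strip()
        if not rel:
            continue
        canon = canonical_relation(rel)
        microbe = str(row["MicrobiotaName"]).strip()
        if canon == "positively_correlated_with":
            exact_pos.add(microbe)
        if canon == "negatively_correlated_with":
            exact_neg.add(microbe)
        meta = schema.relation(rel)
        if meta.polarity == "positive" and meta.significant:
            significant_pos.add(microbe)
    return {
        "positively_correlated_with": exact_pos,
        "negatively_correlated_with": exact_neg,
        "significant_positive": significant_pos,
    }


def table2_fixture(out_dir: str | Path | None = None) -> dict:
    """Association-table fixture: the table (written to ``out_dir`` when
    given) plus the expected query-case-1 answer sets."""
    df = table2_table()
    schema = default_schema()
    out: dict = {"table": df, "expected": _expected_q1_sets(df, schema)}
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        path = out_dir / "table2_fe_associations.tsv"
        shutil.copyfile(data_path("table2_fe_associations.tsv"), path)
        out["path"] = path
    return out


def querycase_graph(schema: OntologySchema | None = None) -> PropertyGraph:
    """Graph holding the printed query-case path triples (cases 4 and 5)."""
    if schema is None:
        schema = default_schema()
    triples, report = parse_annotation_export(data_path("querycase_triples.json"), schema)
    if report.n_rejected:
        raise AssertionError(f"query-case fixture has schema rejects: {report.rejects}")
    graph = PropertyGraph("querycase")
    graph.add_triples(triples, schema=schema)
    return graph


def metabolite_graph(schema: OntologySchema | None = None) -> PropertyGraph:
    """Microbe→metabolite (produce) and metabolite→pathway (involved_in)
    fixture edges, plus the curated feed-efficiency associations — the input
    shape of query case 2."""
    graph = table2_graph(schema)
    graph.name = "pgmDatabase"
    produce = map_metabolite_table(
        read_pair_table(
            data_path("gutmgene_metabolites.tsv"), data_path("colmap_gutmgene.yaml")
        )
    )
    involved = map_pathway_table(
        read_pair_table(data_path("kegg_pathways.tsv"), data_path("colmap_kegg.yaml"))
    )
    graph.add_triples(produce, schema=schema or default_schema())
    graph.add_triples(involved, schema=schema or default_schema())
    return graph


def origins_path() -> Path:
    return data_path("origins_synthetic.tsv")


def qa_paths() -> tuple[Path, Path]:
    """(expected, returned) QA benchmark files."""
    return data_path("qa_synthetic_expected.json"), data_path("qa_synthetic_returned.json")


_RANDOM_TYPES = (
    "MicrobiotaName",
    "MetabolitesName",
    "MetabolismName",
    "ExperimentGroup",
    "ExperimentDesign",
    "GeneName",
)


def _type_for(name: str) -> str:
    # stable across graphs so that shared names collapse on merge
    return _RANDOM_TYPES[sum(name.encode()) % len(_RANDOM_TYPES)]


def random_kb(
    n_nodes: int,
    n_triples: int,
    node_name_pool: list[str] | None = None,
    seed: int = 0,
    name: str = "random",
    schema: OntologySchema | None = None,
) -> PropertyGraph:
    """Deterministic random knowledge base with exact node and triple counts.

    Node names come from ``node_name_pool`` (topped up with generated names if
    short); each node's entity type is a pure function of its name, so two
    random KBs sharing pool names share node keys — which makes merge overlap
    controllable. Every edge gets a unique provenance string, so edge keys
    are distinct within and across differently-named or differently-seeded
    KBs.
    """
    if n_triples > 0 and n_nodes == 0:
        raise ValueError("cannot place triples in a graph with no nodes")
    rng = random.Random(seed)
    if schema is None:
        schema = default_schema()
    relations = sorted(schema.relations)
    names = list(node_name_pool or [])[:n_nodes]
    while len(names) < n_nodes:
        names.append(f"{name} entity {len(names):06d}")
    graph = PropertyGraph(name)
    for n in names:
        graph.add_node(n, _type_for(n))
    for j in range(n_triples):
        s = names[rng.randrange(n_nodes)]
        o = names[rng.randrange(n_nodes)]
        graph.add_triple(
            Triple(
                subject=s,
                subject_type=_type_for(s),
                relation=rng.choice(relations),
                object=o,
                object_type=_type_for(o),
                source=f"{name}:{seed}:{j}",
            )
        )
    assert graph.n_nodes == n_nodes and graph.n_triples == n_triples
    return graph


def table1_trio(seed: int = 0) -> list[PropertyGraph]:
    """Three synthetic KBs at the sizes of the curated, mention-derived and
    database-derived bases, with exactly :data:`TABLE1_SHARED_NODES` node
    keys shared between the first two (so the merged node count is the sum
    minus that overlap) and provenance-distinct edges throughout."""
    shared = [f"shared entity {i:04d}" for i in range(TABLE1_SHARED_NODES)]
    graphs = []
    for kb_i, (kb_name, (n_nodes, n_triples)) in enumerate(sorted(TABLE1_SIZES.items())):
        pool = list(shared) if kb_name in ("pgmReading", "pgmPubtator") else []
        pool += [f"{kb_name} entity {i:06d}" for i in range(n_nodes - len(pool))]
        graphs.append(
            random_kb(
                n_nodes,
                n_triples,
                node_name_pool=pool,
                seed=seed + kb_i,
                name=kb_name,
            )
        )
    return graphs


_SPECIES_POOL = (
    ("Lactobacillus", "1578"),
    ("Bifidobacterium", "1678"),
    ("Bacteroides", "816"),
    ("Clostridium butyricum", "1492"),
    ("Prevotella copri", "165179"),
    ("Escherichia coli", "562"),
    ("Blautia", "572511"),
    ("Faecalibacterium", "216851"),
)


def synthetic_pubtator(n_docs: int, mentions_per_doc: int = 2, seed: int = 0) -> str:
    """Well-formed random PubTator text whose annotation offsets slice the
    document text (title + " " + abstract) to the mention exactly."""
    rng = random.Random(seed)
    docs = []
    for i in range(n_docs):
        pmid = str(30000000 + i)
        title = f"Gut microbiota survey {i} in growing pigs."
        mentions = [rng.choice(_SPECIES_POOL) for _ in range(mentions_per_doc)]
        abstract = "We examined "
        base = len(title) + 1  # offsets are into title + " " + abstract
        annotations = []
        for j, (mention, concept) in enumerate(mentions):
            start = base + len(abstract)
            abstract += mention
            annotations.append(
                PubtatorAnnotation(
                    pmid=pmid,
                    start=start,
                    end=start + len(mention),
                    mention=mention,
                    mention_type="Species",
                    concept_id=concept,
                )
            )
            abstract += " and " if j < len(mentions) - 1 else ""
        abstract += " in weaned piglets."
        docs.append(
            PubtatorDocument(pmid=pmid, title=title, abstract=abstract, annotations=annotations)
        )
    return serialize_pubtator(docs)


def write_all(out_dir: str | Path) -> list[Path]:
    """Copy every packaged fixture file into ``out_dir``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for name in _DATA_FILES:
        dst = out_dir / name
        shutil.copyfile(data_path(name), dst)
        written.append(dst)
    return written
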