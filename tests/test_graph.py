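"""Property graph: node identity, edge provenance, merge algebra, stats."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pgmkit import fixtures as fx
from pgmkit.graph import (
    IngestReport,
    PropertyGraph,
    SchemaViolation,
    Triple,
    merge,
    name_key,
    normalize_name,
    stats,
)


def _t(subject, relation, obj, source="unknown", **attrs):
    return Triple(
        subject=subject,
        subject_type="MicrobiotaName",
        relation=relation,
        object=obj,
        object_type="FeedEfficiency",
        source=source,
        attributes=tuple(sorted({k: str(v) for k, v in attrs.items()}.items())),
    )


def test_add_triple_creates_endpoints_and_is_provenance_aware(schema):
    g = PropertyGraph("pgmReading")
    base = _t("Lactobacillus", "positively_correlated_with", "Feed efficiency", "31291967")
    assert g.add_triple(base, schema=schema)
    assert (g.n_nodes, g.n_triples) == (2, 1)
    # identical (subject, relation, object, source) tuple: no-op
    assert not g.add_triple(base, schema=schema)
    assert g.n_triples == 1
    # same assertion under a second PMID is new evidence, not a duplicate
    assert g.add_triple(
        _t("Lactobacillus", "positively_correlated_with", "Feed efficiency", "7"),
        schema=schema,
    )
    assert (g.n_nodes, g.n_triples) == (2, 2)


def test_schema_violations_raise_or_go_to_the_report(schema):
    g = PropertyGraph()
    bad = _t("Lactobacillus", "frobnicates", "Feed efficiency")
    with pytest.raises(SchemaViolation, match="frobnicates"):
        g.add_triple(bad, schema=schema)
    report = IngestReport()
    assert not g.add_triple(bad, schema=schema, report=report)
    assert report.n_rejected == 1 and g.n_triples == 0
    # explicit bypass admits the triple but counts it
    assert g.add_triple(bad, schema=schema, report=report, validate=False)
    assert report.bypassed == 1 and g.n_triples == 1


def test_name_normalization_merges_spelling_variants():
    g = PropertyGraph()
    g.add_triple(_t("Escherichia–Shigella", "correlated_with", "Feed efficiency", "a"))
    g.add_triple(_t("  escherichia-shigella ", "correlated_with", "Feed efficiency", "b"))
    assert g.n_nodes == 2 and g.n_triples == 2
    assert normalize_name(normalize_name("Escherichia–Shigella")) == normalize_name(
        "Escherichia–Shigella"
    )
    assert name_key("Escherichia–Shigella") == name_key("escherichia-shigella")


def test_merge_identity_and_order_insensitivity():
    a = fx.random_kb(12, 30, seed=5, name="a")
    b = fx.random_kb(9, 20, seed=6, name="b")
    c = fx.random_kb(7, 15, seed=7, name="c")
    assert merge([a]) == a
    assert merge([a, b, c]) == merge([c, b, a])
    assert merge([merge([a, b]), c]) == merge([a, merge([b, c])])


@settings(max_examples=40, derandomize=True, deadline=None)
@given(
    n1=st.integers(1, 15),
    n2=st.integers(1, 15),
    k=st.integers(0, 10),
    seed=st.integers(0, 10_000),
)
def test_merge_node_union_matches_set_arithmetic(n1, n2, k, seed):
    """Two KBs sharing exactly k node keys merge to n1 + n2 - k nodes."""
    k = min(k, n1, n2)
    shared = [f"shared {i}" for i in range(k)]
    a = fx.random_kb(n1, 2 * n1, node_name_pool=shared, seed=seed, name="a")
    b = fx.random_kb(n2, 2 * n2, node_name_pool=shared, seed=seed + 1, name="b")
    merged = merge([a, b])
    # brute-force union of the key sets
    assert merged.n_nodes == len(set(a.node_keys()) | set(b.node_keys()))
    assert merged.n_nodes == n1 + n2 - k
    # provenance-distinct edges stay additive
    assert merged.n_triples == a.n_triples + b.n_triples


def test_stats_recomputed_from_contents(table2_graph):
    empty = PropertyGraph()
    assert stats(empty)["nodes"] == 0 and stats(empty)["triples"] == 0
    s = stats(table2_graph)
    assert s["nodes"] == len(list(table2_graph.nodes()))
    assert s["triples"] == len(list(table2_graph.triples()))
    assert sum(s["node_types"].values()) == s["nodes"]
    assert sum(s["relations"].values()) == s["triples"]


def test_table2_stats_match_independent_row_scan(table2_graph):
    """Node/triple counts equal a direct line-by-line count over the fixture
    file, independent of the graph machinery."""
    rows = fx.data_path("table2_fe_associations.tsv").read_text(encoding="utf-8").splitlines()[1:]
    microbes, taxa, phenos = set(), set(), set()
    relation_edges = set()
    belong_edges = set()
    for line in rows:
        taxonomy, pmid, microbe, relation, phenotype = line.split("\t")
        microbes.add(name_key(microbe))
        taxa.add(name_key(taxonomy))
        phenos.add(name_key(phenotype))
        relation_edges.add(
            (name_key(microbe), (relation or "correlated_with").casefold(), pmid, not relation)
        )
        belong_edges.add((name_key(microbe), name_key(taxonomy)))
    s = stats(table2_graph)
    assert s["nodes"] == len(microbes) + len(taxa) + len(phenos)
    assert s["triples"] == len(relation_edges) + len(belong_edges)


def test_triples_iterate_deterministically(table2_graph):
    assert list(table2_graph.triples()) == list(table2_graph.copy().triples())
    assert table2_graph.node_keys() == sorted(table2_graph.node_keys())


def test_empty_endpoints_are_rejected():
    with pytest.raises(ValueError, match="empty"):
        _t("   ", "correlated_with", "Feed efficiency")
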