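"""Pattern matcher vs brute-force enumeration; the five canned query cases;
Cypher emission round-trips."""

import random

import pytest

from conftest import brute_force_match, reachability_oracle

from pgmkit import fixtures as fx
from pgmkit.graph import PropertyGraph, Triple
from pgmkit.query import (
    EdgeConstraint,
    NodeConstraint,
    PatternError,
    QueryPattern,
    emit_cypher,
    match_pattern,
    parse_cypher_pattern,
    parse_pattern_file,
    q1_fe_microbes,
    q2_metabolites_pathways,
    q3_significant_factors,
    q4_additive_path,
    q5_breed_path,
)

Q4_MICROBES = {
    "Clostridium disporicum",
    "Lactobacillus gasseri",
    "Roseburia",
    "Streptococcus",
    "Lactobacillus",
    "Bacteroidetes",
    "Firmicutes",
}


# ---------------------------------------------------------------------------
# generic matcher
# ---------------------------------------------------------------------------


def test_single_hop_pattern_on_querycase_fixture(querycase_graph, schema):
    pattern = QueryPattern(
        nodes=(
            NodeConstraint("n1", "FeedFermentationType", "fermented spent mushroom substrates"),
            NodeConstraint("m1", "ExperimentDesign"),
        ),
        edges=(EdgeConstraint("n1", "m1", relation="belong_to"),),
        projection=("m1",),
    )
    result = match_pattern(querycase_graph, pattern, schema)
    assert result.column("m1") == ["fed basal diets supplemented with 3% FSMS"]


def test_any_pattern_on_empty_graph_is_empty():
    pattern = QueryPattern(nodes=(NodeConstraint("n", "MicrobiotaName"),))
    assert len(match_pattern(PropertyGraph(), pattern)) == 0


def test_unknown_entity_type_in_pattern_is_an_error(querycase_graph, schema):
    pattern = QueryPattern(nodes=(NodeConstraint("n", "NotAType"),))
    with pytest.raises(PatternError, match="NotAType"):
        match_pattern(querycase_graph, pattern, schema)


def test_pattern_validation_rejects_disconnected_and_undeclared():
    with pytest.raises(PatternError, match="undeclared"):
        QueryPattern(
            nodes=(NodeConstraint("a"),), edges=(EdgeConstraint("a", "ghost"),)
        )
    with pytest.raises(PatternError, match="connected"):
        QueryPattern(nodes=(NodeConstraint("a"), NodeConstraint("b")))


def test_homomorphic_semantics_allow_two_variables_on_one_node():
    g = PropertyGraph()
    g.add_triple(
        Triple(
            subject="A", subject_type="MicrobiotaName", relation="equal_to",
            object="A", object_type="MicrobiotaName", source="x",
        )
    )
    pattern = QueryPattern(
        nodes=(NodeConstraint("p", "MicrobiotaName"), NodeConstraint("q", "MicrobiotaName")),
        edges=(EdgeConstraint("p", "q", relation="equal_to"),),
    )
    assert len(match_pattern(g, pattern)) == 1  # p and q both bind A


def _random_pattern(rng, graph, schema):
    types = sorted({k.entity_type for k in graph.node_keys()})
    relations = sorted({t.relation for t in graph.triples()}) or ["belong_to"]
    n_vars = rng.choice([1, 2, 2, 3])
    nodes = []
    for i in range(n_vars):
        etype = rng.choice(types + [None])
        name = None
        if rng.random() < 0.2:
            key = rng.choice(graph.node_keys())
            name = graph.display_name(key)
            etype = key.entity_type if rng.random() < 0.5 else None
        nodes.append(NodeConstraint(f"v{i}", etype, name))
    edges = []
    for i in range(1, n_vars):  # chain keeps the pattern connected
        edges.append(
            EdgeConstraint(
                f"v{rng.randrange(i)}",
                f"v{i}",
                relation=rng.choice(relations + [None]),
                direction=rng.choice(["out", "in"]),
            )
        )
    return QueryPattern(tuple(nodes), tuple(edges))


@pytest.mark.parametrize("block", range(10))
def test_match_pattern_equals_brute_force_enumeration(block, schema):
    """200 seeded random (graph, pattern) pairs on graphs of up to 40 nodes."""
    for inner in range(20):
        seed = block * 20 + inner
        rng = random.Random(seed)
        n_nodes = rng.randint(3, 40) if rng.random() < 0.3 else rng.randint(3, 14)
        g = fx.random_kb(n_nodes, rng.randint(0, 3 * n_nodes), seed=seed)
        pattern = _random_pattern(rng, g, schema)
        got = match_pattern(g, pattern, schema)
        got_rows = {tuple(row[v] for v in pattern.projection) for row in got.bindings}
        assert got_rows == brute_force_match(g, pattern, schema), f"seed {seed}"
        # and the returned rows are distinct and sorted
        as_tuples = [tuple(row[v] for v in pattern.projection) for row in got.bindings]
        assert as_tuples == sorted(set(as_tuples))


def test_results_stable_under_reserialization(querycase_graph, schema):
    from pgmkit.io import export_graphml, import_graphml

    reloaded = import_graphml(export_graphml(querycase_graph))
    for graph in (querycase_graph, reloaded):
        assert q4_additive_path(graph, "fermented spent mushroom substrates") == Q4_MICROBES


# ---------------------------------------------------------------------------
# canned cases
# ---------------------------------------------------------------------------


def test_q1_exact_label_counts(table2_graph):
    assert len(q1_fe_microbes(table2_graph, relation="Positively_correlated_with")) == 25
    assert len(q1_fe_microbes(table2_graph, relation="Negatively_correlated_with")) == 16
    assert q1_fe_microbes(PropertyGraph()) == []


def test_q1_agrees_with_generic_pattern_form(table2_graph, schema):
    pattern = QueryPattern(
        nodes=(
            NodeConstraint("m", "MicrobiotaName"),
            NodeConstraint("fe", "FeedEfficiency", "Feed efficiency"),
        ),
        edges=(EdgeConstraint("m", "fe", relation="positively_correlated_with"),),
        projection=("m",),
    )
    generic = match_pattern(table2_graph, pattern, schema).column("m")
    canned = [r["microbe"] for r in q1_fe_microbes(table2_graph, relation="Positively_correlated_with")]
    assert generic == canned


def test_q1_polarity_filter_matches_brute_force_on_randomized_labels(schema):
    rng = random.Random(9)
    relations = sorted(schema.relations)
    g = PropertyGraph()
    rows = []
    for i in range(120):
        rel = rng.choice(relations)
        microbe = f"microbe {rng.randrange(40)}"
        rows.append((microbe, rel))
        g.add_triple(
            Triple(
                subject=microbe, subject_type="MicrobiotaName", relation=rel,
                object="Feed efficiency", object_type="FeedEfficiency", source=str(i),
            )
        )
    for polarity, significant in [("positive", True), ("negative", None), (None, True)]:
        expected = set()
        for microbe, rel in rows:
            meta = schema.relation(rel)
            if polarity is not None and meta.polarity != polarity:
                continue
            if significant is not None and meta.significant != significant:
                continue
            expected.add(microbe)
        got = {
            r["microbe"]
            for r in q1_fe_microbes(g, polarity=polarity, significant=significant, schema=schema)
        }
        assert got == expected


def test_q2_degree_filters_match_brute_force_counting():
    g = fx.metabolite_graph()
    res = q2_metabolites_pathways(g, min_producers=2, min_metabolites=2)
    assert "Butyrate" in res["metabolites"]
    assert len(res["metabolites"]["Butyrate"]) == 7
    # brute-force recount from the raw fixture tables
    from pgmkit.databases import read_pair_table

    produce = read_pair_table(
        fx.data_path("gutmgene_metabolites.tsv"), fx.data_path("colmap_gutmgene.yaml")
    )
    fe_microbes = {r["microbe"] for r in q1_fe_microbes(g)}
    producer_count = {}
    for microbe, metabolite in set(produce):
        if microbe in fe_microbes:
            producer_count[metabolite] = producer_count.get(metabolite, 0) + 1
    assert set(res["metabolites"]) == {m for m, c in producer_count.items() if c >= 2}
    pathways = read_pair_table(
        fx.data_path("kegg_pathways.tsv"), fx.data_path("colmap_kegg.yaml")
    )
    member_count = {}
    for metabolite, pathway in set(pathways):
        if metabolite in producer_count:
            member_count[pathway] = member_count.get(pathway, 0) + 1
    assert set(res["pathways"]) == {p for p, c in member_count.items() if c >= 2}
    # degenerate threshold empties the result
    assert q2_metabolites_pathways(g, min_producers=10**6)["metabolites"] == {}


def test_q3_selects_significant_positive_relations(table2_graph, schema):
    report = q3_significant_factors(table2_graph, schema)
    microbes = {r["microbe"] for r in report["pgmReading"]}
    assert {
        "Bacteroidales",
        "Bifidobacterium",
        "Clostridiales",
        "Colinsella",
        "Lactobacillus",
        "Paraprevotella clara",
        "Prevotella copri",
    } <= microbes
    # every selected relation is significant and positive
    for row in report["pgmReading"]:
        for rel in row["relations"]:
            meta = schema.relation(rel)
            assert meta.significant and meta.polarity == "positive"


def test_q3_on_nonsignificant_graph_is_empty(schema):
    g = PropertyGraph("kb")
    g.add_triple(
        Triple(
            subject="Prevotella", subject_type="MicrobiotaName", relation="correlated_with",
            object="Feed efficiency", object_type="FeedEfficiency", source="1",
        )
    )
    assert q3_significant_factors(g, schema) == {"kb": []}


def test_q4_and_q5_on_fixture(querycase_graph):
    assert q4_additive_path(querycase_graph, "fermented spent mushroom substrates") == Q4_MICROBES
    assert q4_additive_path(querycase_graph, "no such additive") == set()
    assert q5_breed_path(querycase_graph, "Duroc × Large White × Landrace") == {
        "Bacteroidetes",
        "Firmicutes",
    }
    assert q5_breed_path(querycase_graph, "no such breed") == set()


@pytest.mark.parametrize("seed", range(25))
def test_q4_q5_match_reachability_oracle_on_random_path_fixtures(seed, schema):
    rng = random.Random(seed)
    g = PropertyGraph()

    def add(s, st, r, o, ot):
        g.add_triple(
            Triple(subject=s, subject_type=st, relation=r, object=o, object_type=ot,
                   source=f"s{rng.randrange(10)}")
        )

    additives = [f"additive {i}" for i in range(3)]
    breeds = [f"breed {i}" for i in range(2)]
    designs = [f"design {i}" for i in range(5)]
    groups = [f"group {i}" for i in range(6)]
    microbes = [f"microbe {i}" for i in range(8)]
    for _ in range(rng.randint(5, 25)):
        kind = rng.randrange(4)
        if kind == 0:
            add(rng.choice(additives), "FeedadditivesName", "belong_to",
                rng.choice(designs), "ExperimentDesign")
        elif kind == 1:
            add(rng.choice(designs), "ExperimentDesign", "belong_to",
                rng.choice(breeds), "SwineBreed")
        elif kind == 2:
            add(rng.choice(groups), "ExperimentGroup", "belong_to",
                rng.choice(designs), "ExperimentDesign")
        else:
            add(rng.choice(groups), "ExperimentGroup",
                rng.choice(["influence", "correlated_with"]),
                rng.choice(microbes), "MicrobiotaName")
    for additive in additives:
        assert q4_additive_path(g, additive, schema=schema) == reachability_oracle(
            g, additive, anchor_reversed=False
        )
    for breed in breeds:
        assert q5_breed_path(g, breed, schema=schema) == reachability_oracle(
            g, breed, anchor_reversed=True
        )


def test_relaxed_mode_widens_the_microbe_hop(schema):
    g = PropertyGraph()
    for rel in ("influence", "increase"):
        g.add_triple(
            Triple(subject="grp", subject_type="ExperimentGroup", relation=rel,
                   object=f"microbe-{rel}", object_type="MicrobiotaName", source="x")
        )
    g.add_triple(
        Triple(subject="add", subject_type="FeedadditivesName", relation="belong_to",
               object="des", object_type="ExperimentDesign", source="x")
    )
    g.add_triple(
        Triple(subject="grp", subject_type="ExperimentGroup", relation="belong_to",
               object="des", object_type="ExperimentDesign", source="x")
    )
    assert q4_additive_path(g, "add", schema=schema) == {"microbe-influence"}
    assert q4_additive_path(g, "add", relaxed=True, schema=schema) == {
        "microbe-influence",
        "microbe-increase",
    }


# ---------------------------------------------------------------------------
# Cypher text
# ---------------------------------------------------------------------------


def test_emitted_first_hop_matches_reference_text():
    pattern = QueryPattern(
        nodes=(
            NodeConstraint("n1", "FeedFermentationType", "fermented spent mushroom substrates"),
            NodeConstraint("m1", "ExperimentDesign"),
        ),
        edges=(EdgeConstraint("n1", "m1"),),
        projection=("n1", "m1"),
    )
    got = emit_cypher(pattern)
    want = (
        "MATCH (n1:FeedFermentationType{name:'fermented spent mushroom substrates'})"
        "-[r1]->(m1:ExperimentDesign) return n1, m1"
    )
    assert " ".join(got.split()) == " ".join(want.split())


def test_single_node_pattern_emission():
    pattern = QueryPattern(nodes=(NodeConstraint("n1", "MicrobiotaName"),))
    assert emit_cypher(pattern) == "MATCH (n1:MicrobiotaName) return n1"


def test_parse_of_reference_query_line():
    pattern = parse_cypher_pattern(
        "MATCH (n1:FeedFermentationType{name:'fermented spent mushroom substrates'})"
        "-[r1] → (m1:ExperimentDesign) return n1, r1, m1"
    )
    assert pattern.nodes[0].name == "fermented spent mushroom substrates"
    assert pattern.edges == (EdgeConstraint("n1", "m1"),)
    assert pattern.projection == ("n1", "m1")


@pytest.mark.parametrize("seed", range(30))
def test_emit_parse_round_trip_on_random_patterns(seed):
    rng = random.Random(seed)
    n_vars = rng.randint(1, 4)
    nodes = [
        NodeConstraint(
            f"v{i}",
            rng.choice(["MicrobiotaName", "ExperimentDesign", None]),
            rng.choice([None, f"name {i}"]),
        )
        for i in range(n_vars)
    ]
    edges = tuple(
        EdgeConstraint(
            f"v{rng.randrange(i)}",
            f"v{i}",
            relation=rng.choice(["belong_to", "influence", None]),
            direction=rng.choice(["out", "in"]),
        )
        for i in range(1, n_vars)
    )
    pattern = QueryPattern(tuple(nodes), edges, tuple(f"v{i}" for i in range(n_vars)))
    assert parse_cypher_pattern(emit_cypher(pattern)) == pattern


def test_metadata_filtered_edges_have_no_cypher_form():
    pattern = QueryPattern(
        nodes=(NodeConstraint("a"), NodeConstraint("b")),
        edges=(EdgeConstraint("a", "b", category=("regulation",)),),
    )
    with pytest.raises(PatternError, match="Cypher"):
        emit_cypher(pattern)


def test_pattern_file_round_trips_through_matcher(querycase_graph, schema):
    text = (
        '# additive to experiment design\n'
        'node n1 FeedFermentationType name="fermented spent mushroom substrates"\n'
        "node m1 ExperimentDesign\n"
        "edge n1 belong_to m1\n"
        "return m1\n"
    )
    pattern = parse_pattern_file(text)
    result = match_pattern(querycase_graph, pattern, schema)
    assert result.column("m1") == ["fed basal diets supplemented with 3% FSMS"]
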