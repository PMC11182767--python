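"""Shared fixtures and independent brute-force oracles.

The oracles deliberately avoid the library's join/traversal machinery: the
pattern oracle enumerates every assignment of pattern variables to graph
nodes with ``itertools.product``; the path oracle is a plain breadth-first
expansion of the query-case semantics.
"""

from __future__ import annotations

import itertools

import pytest

from pgmkit import fixtures as fx
from pgmkit.graph import PropertyGraph, name_key
from pgmkit.ontology import OntologySchema, canonical_relation, default_schema
from pgmkit.query import QueryPattern


@pytest.fixture(scope="session")
def schema() -> OntologySchema:
    return default_schema()

@pytest.fixture(scope="session")
def extended_schema() -> OntologySchema:
    return default_schema(with_mention_extensions=True)


@pytest.fixture(scope="session")
def table2_graph() -> PropertyGraph:
    return fx.table2_graph()


@pytest.fixture(scope="session")
def querycase_graph() -> PropertyGraph:
    return fx.querycase_graph()


# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------


def _triple_ok(triple, constraint, schema) -> bool:
    if constraint.relation is not None:
        if canonical_relation(triple.relation) != canonical_relation(constraint.relation):
            return False
    if (
        constraint.category is not None
        or constraint.polarity is not None
        or constraint.significant is not None
    ):
        if not schema.has_relation(triple.relation):
            return False
        meta = schema.relation(triple.relation)
        if constraint.category is not None and meta.category not in constraint.category:
            return False
        if constraint.polarity is not None and meta.polarity != constraint.polarity:
            return False
        if constraint.significant is not None and meta.significant != constraint.significant:
            return False
    return True


def brute_force_match(
    graph: PropertyGraph, pattern: QueryPattern, schema: OntologySchema | None = None
) -> set[tuple[str, ...]]:
    """All homomorphic matches by exhaustive enumeration over every variable
    assignment; returns the distinct projected display-name tuples."""
    all_triples = list(graph.triples())
    keys = graph.node_keys()
    rows: set[tuple[str, ...]] = set()
    domains = []
    for nc in pattern.nodes:
        domain = [
            k
            for k in keys
            if (nc.entity_type is None or k.entity_type == nc.entity_type)
            and (nc.name is None or k.name == name_key(nc.name))
        ]
        domains.append(domain)
    for assignment in itertools.product(*domains):
        binding = {nc.var: k for nc, k in zip(pattern.nodes, assignment)}
        ok = True
        for ec in pattern.edges:
            a, b = binding[ec.src], binding[ec.dst]
            if ec.direction == "in":
                a, b = b, a
            if not any(
                t.subject_key == a and t.object_key == b and _triple_ok(t, ec, schema)
                for t in all_triples
            ):
                ok = False
                break
        if ok:
            rows.add(
                tuple(graph.display_name(binding[v]) for v in pattern.projection)
            )
    return rows


def reachability_oracle(
    graph: PropertyGraph, anchor_name: str, anchor_reversed: bool
) -> set[str]:
    """Query-case-4/5 answer by stepwise expansion: anchor → designs via
    belong_to (reversed for the breed case), groups belonging to those
    designs, microbes the groups influence."""
    triples = list(graph.triples())
    anchor = name_key(anchor_name)
    if anchor_reversed:  # designs that belong_to the anchor (breed)
        designs = {
            t.subject_key
            for t in triples
            if canonical_relation(t.relation) == "belong_to"
            and t.object_key.name == anchor
            and t.subject_key.entity_type == "ExperimentDesign"
        }
    else:  # designs the anchor (additive) belongs to
        designs = {
            t.object_key
            for t in triples
            if canonical_relation(t.relation) == "belong_to"
            and t.subject_key.name == anchor
            and t.object_key.entity_type == "ExperimentDesign"
        }
    groups = {
        t.subject_key
        for t in triples
        if canonical_relation(t.relation) == "belong_to"
        and t.object_key in designs
        and t.subject_key.entity_type == "ExperimentGroup"
    }
    return {
        graph.display_name(t.object_key)
        for t in triples
        if canonical_relation(t.relation) == "influence"
        and t.subject_key in groups
        and t.object_key.entity_type == "MicrobiotaName"
    }
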