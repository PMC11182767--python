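"""Provenance-preserving property multigraph.

Nodes are keyed by ``(normalized name, entity type)``; edges are typed triples
that keep their provenance (a PMID or database name) and an attribute map on
the edge itself.  Two design rules follow from how the three knowledge bases
are combined:

* node identity is *name-based* — the same microbe mentioned by two knowledge
  bases collapses to one node (names are compared after trimming, whitespace
  collapsing, dash unification and casefolding, but displayed as first seen);
* edges are never deduplicated across provenance: the same assertion backed by
  two PMIDs is two edges, so triple counts are exactly additive under merge
  whenever edge keys are disjoint.

An edge key is ``(subject key, relation, object key, source, attributes)``;
re-adding an identical edge is a no-op, while the same association reported
under two different case/control conditions stays as two edges.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

from .ontology import OntologySchema, canonical_relation

__all__ = [
    "Triple",
    "NodeKey",
    "PropertyGraph",
    "IngestReport",
    "SchemaViolation",
    "normalize_name",
    "name_key",
    "merge",
    "stats",
]

_DASHES = "‐‑‒–—―−"  # hyphen variants, en/em dash, minus


def normalize_name(name: str) -> str:
    """Display normalization: trim, collapse whitespace, unify dash variants.

    Case is preserved for display; :func:`name_key` adds casefolding for
    identity comparison. Idempotent.
    """
    s = re.sub(r"\s+", " ", name.strip())
    return re.sub(f"[{_DASHES}]", "-", s)


def name_key(name: str) -> str:
    """Identity key for a node name (normalized + casefolded)."""
    return normalize_name(name).casefold()


@dataclass(frozen=True, order=True)
class NodeKey:
    name: str  # casefolded normalized name
    entity_type: str


class SchemaViolation(ValueError):
    """A triple that does not validate against the ontology."""


def _freeze_attributes(attributes: Mapping[str, str] | None) -> tuple[tuple[str, str], ...]:
    if not attributes:
        return ()
    # empty-string values are treated as absent (they would not survive CSV round-trips)
    items = {str(k): str(v) for k, v in attributes.items() if str(v) != ""}
    return tuple(sorted(items.items()))


@dataclass(frozen=True)
class Triple:
    """One provenance-carrying assertion ``subject -relation-> object``.

    ``source`` is a PMID or database name; "unknown" is an explicit sentinel,
    never absent.  ``attributes`` hold per-edge evidence (e.g. Condition,
    Pvalue, Mean(RA)_control) as a frozen sorted item tuple.
    """

    subject: str
    subject_type: str
    relation: str
    object: str
    object_type: str
    source: str = "unknown"
    attributes: tuple[tuple[str, str], ...] = field(default=())

    def __post_init__(self):
        if not normalize_name(self.subject):
            raise ValueError("triple subject is empty after normalization")
        if not normalize_name(self.object):
            raise ValueError("triple object is empty after normalization")
        if not self.source:
            object.__setattr__(self, "source", "unknown")
        if not isinstance(self.attributes, tuple):
            object.__setattr__(self, "attributes", _freeze_attributes(self.attributes))

    @property
    def attribute_map(self) -> dict[str, str]:
        return dict(self.attributes)

    @property
    def subject_key(self) -> NodeKey:
        return NodeKey(name_key(self.subject), self.subject_type)

    @property
    def object_key(self) -> NodeKey:
        return NodeKey(name_key(self.object), self.object_type)

    @property
    def edge_key(self) -> tuple:
        return (
            self.subject_key,
            canonical_relation(self.relation),
            self.object_key,
            self.source,
            self.attributes,
        )

    def validate(self, schema: OntologySchema) -> str | None:
        """Return a rejection reason, or None if the triple is schema-valid."""
        if not schema.has_detail_type(self.subject_type):
            return f"unknown subject type: {self.subject_type!r}"
        if not schema.has_detail_type(self.object_type):
            return f"unknown object type: {self.object_type!r}"
        if not schema.has_relation(self.relation):
            return f"unknown relation: {self.relation!r}"
        return None


@dataclass
class IngestReport:
    """Counts and rejects accumulated while loading triples into a graph."""

    added: int = 0
    duplicates: int = 0
    bypassed: int = 0  # schema-invalid triples admitted with validate=False
    rejects: list[tuple[int | None, Triple | None, str]] = field(default_factory=list)

    def reject(self, position: int | None, triple: Triple | None, reason: str) -> None:
        self.rejects.append((position, triple, reason))

    @property
    def n_rejected(self) -> int:
        return len(self.rejects)

    def to_dict(self) -> dict:
        return {
            "added": self.added,
            "duplicates": self.duplicates,
            "bypassed": self.bypassed,
            "rejected": self.n_rejected,
            "rejects": [
                {"position": pos, "reason": reason}
                for pos, _t, reason in self.rejects
            ],
        }


class PropertyGraph:
    """Multigraph of typed nodes and provenance-carrying edges.

    Iteration over nodes and edges is deterministic (sorted by key); counts
    are always recomputed from contents.  Equality compares contents (nodes
    with display names, and the edge multiset) but not the graph's name, so a
    merge of a single knowledge base equals that knowledge base.
    """

    def __init__(self, name: str = ""):
        self.name = name
        self._nodes: dict[NodeKey, str] = {}  # key -> display name
        self._edges: dict[tuple, Triple] = {}

    # -- mutation ------------------------------------------------------------

    def add_node(self, name: str, entity_type: str) -> NodeKey:
        key = NodeKey(name_key(name), entity_type)
        if key not in self._nodes:
            self._nodes[key] = normalize_name(name)
        return key

    def add_triple(
        self,
        triple: Triple,
        schema: OntologySchema | None = None,
        report: IngestReport | None = None,
        validate: bool = True,
    ) -> bool:
        """Append an edge (and its endpoints). Returns True if the edge is new.

        With a schema and ``validate=True``, schema-invalid triples raise
        :class:`SchemaViolation` — or, when a ``report`` is given, are
        recorded there and skipped.  ``validate=False`` admits them but
        counts the bypass in the report.
        """
        if schema is not None:
            reason = triple.validate(schema)
            if reason is not None:
                if validate:
                    if report is not None:
                        report.reject(None, triple, reason)
                        return False
                    raise SchemaViolation(reason)
                elif report is not None:
                    report.bypassed += 1
        key = triple.edge_key
        if key in self._edges:
            if report is not None:
                report.duplicates += 1
            return False
        self.add_node(triple.subject, triple.subject_type)
        self.add_node(triple.object, triple.object_type)
        self._edges[key] = triple
        if report is not None:
            report.added += 1
        return True

    def add_triples(
        self,
        triples: Iterable[Triple],
        schema: OntologySchema | None = None,
        validate: bool = True,
    ) -> IngestReport:
        report = IngestReport()
        for t in triples:
            self.add_triple(t, schema=schema, report=report, validate=validate)
        return report

    # -- access --------------------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return len(self._nodes)

    @property
    def n_triples(self) -> int:
        return len(self._edges)

    def nodes(self) -> Iterator[tuple[NodeKey, str]]:
        """(key, display name) pairs in sorted key order."""
        for key in sorted(self._nodes):
            yield key, self._nodes[key]

    def node_keys(self) -> list[NodeKey]:
        return sorted(self._nodes)

    def display_name(self, key: NodeKey) -> str:
        return self._nodes[key]

    def has_node(self, name: str, entity_type: str) -> bool:
        return NodeKey(name_key(name), entity_type) in self._nodes

    def triples(self) -> Iterator[Triple]:
        for key in sorted(self._edges):
            yield self._edges[key]

    def edges_from(self, key: NodeKey) -> Iterator[Triple]:
        for t in self.triples():
            if t.subject_key == key:
                yield t

    def edges_to(self, key: NodeKey) -> Iterator[Triple]:
        for t in self.triples():
            if t.object_key == key:
                yield t

    def find_nodes(
        self, name: str | None = None, entity_type: str | None = None
    ) -> list[NodeKey]:
        """Nodes matching an (optional) normalized name and/or entity type."""
        want = name_key(name) if name is not None else None
        out = []
        for key in sorted(self._nodes):
            if want is not None and key.name != want:
                continue
            if entity_type is not None and key.entity_type != entity_type:
                continue
            out.append(key)
        return out

    # -- algebra ---------------------------------------------------------------

    def copy(self, name: str | None = None) -> "PropertyGraph":
        g = PropertyGraph(self.name if name is None else name)
        g._nodes = dict(self._nodes)
        g._edges = dict(self._edges)
        return g

    def __eq__(self, other) -> bool:
        if not isinstance(other, PropertyGraph):
            return NotImplemented
        return self._nodes == other._nodes and set(self._edges) == set(other._edges)

    def __repr__(self) -> str:
        return (
            f"PropertyGraph(name={self.name!r}, nodes={self.n_nodes}, "
            f"triples={self.n_triples})"
        )


def merge(graphs: Iterable[PropertyGraph], name: str = "merged") -> PropertyGraph:
    """Union of knowledge bases: nodes by key, edges by full edge key.

    Cross-KB edges with different provenance are all retained, so the merged
    triple count equals the sum of per-KB counts whenever per-KB edge keys
    are disjoint; the merged node count never exceeds the sum of node counts.
    Display names: first graph (in argument order) wins for a shared key.
    """
    graphs = list(graphs)
    if not graphs:
        raise ValueError("merge requires at least one graph")
    out = PropertyGraph(name)
    for g in graphs:
        for key, display in g.nodes():
            if key not in out._nodes:
                out._nodes[key] = display
        for ekey, t in g._edges.items():
            if ekey not in out._edges:
                out._edges[ekey] = t
    return out


def stats(graph: PropertyGraph) -> dict:
    """Counts record: nodes, triples, and per-type / per-relation histograms."""
    node_types: dict[str, int] = {}
    for key, _ in graph.nodes():
        node_types[key.entity_type] = node_types.get(key.entity_type, 0) + 1
    relations: dict[str, int] = {}
    for t in graph.triples():
        canon = canonical_relation(t.relation)
        relations[canon] = relations.get(canon, 0) + 1
    return {
        "name": graph.name,
        "nodes": graph.n_nodes,
        "triples": graph.n_triples,
        "node_types": dict(sorted(node_types.items())),
        "relations": dict(sorted(relations.items())),
    }
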