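"""Graph-pattern matching and the five canned biological query cases.

The generic matcher finds *homomorphic* matches of a small pattern graph into
the property graph (two pattern variables may bind the same node, matching
Cypher's default semantics).  On top of it sit the five query cases used to
interrogate the feed-efficiency knowledge graph:

1. microbes adjacent to the feed-efficiency node, filtered by relation label,
   polarity or significance;
2. the two-hop chain microbe → metabolite (``produce``) → pathway
   (``involved_in``) with minimum-degree filters;
3. microbes with significant positive relations to feed efficiency, grouped
   by knowledge base;
4. microbes reached from a feed additive through its experiment design and
   experiment groups;
5. microbes reached from a pig breed through the designs applied to it.

Patterns can be emitted as Cypher MATCH text and parsed back (round-trip on
the emitted subset: node labels, exact names, relation labels).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .graph import NodeKey, PropertyGraph, Triple, name_key
from .ontology import OntologySchema, canonical_relation, default_schema

__all__ = [
    "NodeConstraint",
    "EdgeConstraint",
    "QueryPattern",
    "QueryResult",
    "PatternError",
    "match_pattern",
    "q1_fe_microbes",
    "q2_metabolites_pathways",
    "q3_significant_factors",
    "q4_additive_path",
    "q5_breed_path",
    "emit_cypher",
    "parse_cypher_pattern",
    "parse_pattern_file",
    "FE_NODE_NAME",
]

FE_NODE_NAME = "Feed efficiency"


class PatternError(ValueError):
    pass


@dataclass(frozen=True)
class NodeConstraint:
    var: str
    entity_type: str | None = None
    name: str | None = None


@dataclass(frozen=True)
class EdgeConstraint:
    """Constraint on one edge of the pattern.

    ``relation`` filters by exact (canonicalized) label; ``category`` /
    ``polarity`` / ``significant`` filter through the ontology's relation
    metadata instead (requires a schema at match time). ``direction`` is
    "out" (src -> dst, the stored direction) or "in" (inverse traversal).
    """

    src: str
    dst: str
    relation: str | None = None
    category: tuple[str, ...] | None = None
    polarity: str | None = None
    significant: bool | None = None
    direction: str = "out"


@dataclass(frozen=True)
class QueryPattern:
    nodes: tuple[NodeConstraint, ...]
    edges: tuple[EdgeConstraint, ...] = ()
    projection: tuple[str, ...] = ()

    def __post_init__(self):
        declared = [n.var for n in self.nodes]
        if len(set(declared)) != len(declared):
            raise PatternError("duplicate pattern variable")
        declared_set = set(declared)
        for e in self.edges:
            for v in (e.src, e.dst):
                if v not in declared_set:
                    raise PatternError(f"edge references undeclared variable {v!r}")
            if e.direction not in ("out", "in"):
                raise PatternError(f"invalid direction {e.direction!r}")
        if not self.projection:
            object.__setattr__(self, "projection", tuple(declared))
        for v in self.projection:
            if v not in declared_set:
                raise PatternError(f"projection references undeclared variable {v!r}")
        # connectivity (patterns with >1 variable must be linked by edges)
        if len(declared) > 1:
            adj: dict[str, set[str]] = {v: set() for v in declared}
            for e in self.edges:
                adj[e.src].add(e.dst)
                adj[e.dst].add(e.src)
            seen = {declared[0]}
            stack = [declared[0]]
            while stack:
                for nxt in adj[stack.pop()]:
                    if nxt not in seen:
                        seen.add(nxt)
                        stack.append(nxt)
            if seen != declared_set:
                raise PatternError("pattern graph is not connected")

    def node(self, var: str) -> NodeConstraint:
        for n in self.nodes:
            if n.var == var:
                return n
        raise KeyError(var)


@dataclass
class QueryResult:
    """Distinct, deterministically ordered variable bindings.

    ``bindings`` rows map variable -> display name of the bound node;
    ``provenance`` carries, per row, the sorted sources of the matched edges.
    """

    variables: tuple[str, ...]
    bindings: list[dict[str, str]] = field(default_factory=list)
    provenance: list[tuple[str, ...]] = field(default_factory=list)

    def column(self, var: str) -> list[str]:
        return [row[var] for row in self.bindings]

    def __len__(self) -> int:
        return len(self.bindings)


def _node_candidates(graph: PropertyGraph, nc: NodeConstraint) -> list[NodeKey]:
    return graph.find_nodes(name=nc.name, entity_type=nc.entity_type)


def _edge_admits(
    ec: EdgeConstraint, triple: Triple, schema: OntologySchema | None
) -> bool:
    if ec.relation is not None:
        if canonical_relation(triple.relation) != canonical_relation(ec.relation):
            return False
    if ec.category is not None or ec.polarity is not None or ec.significant is not None:
        if schema is None:
            raise PatternError(
                "relation category/polarity/significance filters require a schema"
            )
        if not schema.has_relation(triple.relation):
            return False
        meta = schema.relation(triple.relation)
        if ec.category is not None and meta.category not in ec.category:
            return False
        if ec.polarity is not None and meta.polarity != ec.polarity:
            return False
        if ec.significant is not None and meta.significant != ec.significant:
            return False
    return True


def match_pattern(
    graph: PropertyGraph,
    pattern: QueryPattern,
    schema: OntologySchema | None = None,
) -> QueryResult:
    """All homomorphic matches of ``pattern`` into ``graph``.

    Equivalent to exhaustive enumeration over every assignment of pattern
    variables to graph nodes; implemented as a backtracking join over the
    edge constraints. Unknown entity types in the pattern are an error when a
    schema is provided.
    """
    if schema is not None:
        for nc in pattern.nodes:
            if nc.entity_type is not None and not schema.has_detail_type(nc.entity_type):
                raise PatternError(f"pattern uses unknown entity type {nc.entity_type!r}")

    candidates = {nc.var: _node_candidates(graph, nc) for nc in pattern.nodes}
    # group stored edges by (subject_key, object_key) once
    by_ends: dict[tuple[NodeKey, NodeKey], list[Triple]] = {}
    for t in graph.triples():
        by_ends.setdefault((t.subject_key, t.object_key), []).append(t)

    rows: list[tuple[dict[str, NodeKey], tuple[str, ...]]] = []

    order = [nc.var for nc in pattern.nodes]

    def edge_endpoints(ec: EdgeConstraint, binding: Mapping[str, NodeKey]):
        a, b = binding[ec.src], binding[ec.dst]
        return (a, b) if ec.direction == "out" else (b, a)

    def extend(idx: int, binding: dict[str, NodeKey]):
        if idx == len(order):
            # verify every edge constraint has at least one admissible triple
            sources: set[str] = set()
            for ec in pattern.edges:
                matched = [
                    t
                    for t in by_ends.get(edge_endpoints(ec, binding), [])
                    if _edge_admits(ec, t, schema)
                ]
                if not matched:
                    return
                sources.update(t.source for t in matched)
            rows.append((dict(binding), tuple(sorted(sources))))
            return
        var = order[idx]
        for key in candidates[var]:
            binding[var] = key
            # prune: edges whose both endpoints are bound must be satisfiable
            ok = True
            for ec in pattern.edges:
                if ec.src in binding and ec.dst in binding:
                    if not any(
                        _edge_admits(ec, t, schema)
                        for t in by_ends.get(edge_endpoints(ec, binding), [])
                    ):
                        ok = False
                        break
            if ok:
                extend(idx + 1, binding)
            del binding[var]

    extend(0, {})

    # distinct projected rows, sorted lexicographically by bound node names
    result = QueryResult(variables=pattern.projection)
    seen: set[tuple[str, ...]] = set()
    projected = []
    for binding, sources in rows:
        names = tuple(graph.display_name(binding[v]) for v in pattern.projection)
        if names in seen:
            continue
        seen.add(names)
        projected.append((names, sources))
    for names, sources in sorted(projected):
        result.bindings.append(dict(zip(pattern.projection, names)))
        result.provenance.append(sources)
    return result


# ---------------------------------------------------------------------------
# canned query cases
# ---------------------------------------------------------------------------


def _fe_nodes(graph: PropertyGraph) -> list[NodeKey]:
    nodes = graph.find_nodes(name=FE_NODE_NAME)
    if not nodes:
        nodes = graph.find_nodes(entity_type="FeedEfficiency")
    return nodes


def q1_fe_microbes(
    graph: PropertyGraph,
    relation: str | None = None,
    polarity: str | None = None,
    significant: bool | None = None,
    schema: OntologySchema | None = None,
) -> list[dict]:
    """Distinct microbes adjacent to the feed-efficiency node.

    ``relation`` selects one exact (case-insensitive) label; ``polarity`` /
    ``significant`` filter through relation metadata instead.  A microbe
    counts once however many PMIDs assert the relation; all its sources are
    reported.
    """
    if schema is None and (polarity is not None or significant is not None):
        schema = default_schema()
    fe = set(_fe_nodes(graph))
    records: dict[str, dict] = {}
    for t in graph.triples():
        if t.object_key not in fe or t.subject_type != "MicrobiotaName":
            continue
        if relation is not None and canonical_relation(t.relation) != canonical_relation(relation):
            continue
        if polarity is not None or significant is not None:
            if not schema.has_relation(t.relation):
                continue
            meta = schema.relation(t.relation)
            if polarity is not None and meta.polarity != polarity:
                continue
            if significant is not None and meta.significant != significant:
                continue
        display = graph.display_name(t.subject_key)
        rec = records.setdefault(
            display, {"microbe": display, "relations": set(), "sources": set()}
        )
        rec["relations"].add(canonical_relation(t.relation))
        rec["sources"].add(t.source)
    return [
        {
            "microbe": m,
            "relations": tuple(sorted(rec["relations"])),
            "sources": tuple(sorted(rec["sources"])),
        }
        for m, rec in sorted(records.items())
    ]


def q2_metabolites_pathways(
    graph: PropertyGraph,
    min_producers: int = 2,
    min_metabolites: int = 2,
) -> dict:
    """Two-hop result microbe → metabolite → pathway.

    Starts from microbes adjacent to the feed-efficiency node, follows
    ``produce`` edges, keeps metabolites produced by at least
    ``min_producers`` distinct such microbes, and keeps pathways
    (``involved_in``) involving at least ``min_metabolites`` distinct reached
    metabolites.
    """
    microbes = {r["microbe"] for r in q1_fe_microbes(graph)}
    microbe_keys = {name_key(m) for m in microbes}
    producers: dict[str, set[str]] = {}
    for t in graph.triples():
        if canonical_relation(t.relation) == "produce" and t.subject_key.name in microbe_keys:
            producers.setdefault(t.object, set()).add(t.subject)
    metabolites = {
        m: sorted(ps) for m, ps in producers.items() if len(ps) >= min_producers
    }
    reached_keys = {name_key(m) for m in producers}
    pathway_members: dict[str, set[str]] = {}
    for t in graph.triples():
        if canonical_relation(t.relation) == "involved_in" and t.subject_key.name in reached_keys:
            pathway_members.setdefault(t.object, set()).add(t.subject)
    pathways = {
        p: sorted(ms)
        for p, ms in pathway_members.items()
        if len(ms) >= min_metabolites
    }
    return {
        "microbes": sorted(microbes),
        "metabolites": dict(sorted(metabolites.items())),
        "pathways": dict(sorted(pathways.items())),
    }


def q3_significant_factors(
    graphs: PropertyGraph | Sequence[PropertyGraph],
    schema: OntologySchema | None = None,
) -> dict[str, list[dict]]:
    """Microbes with significant positive relations to feed efficiency,
    grouped per knowledge base (pass the component graphs to get one group
    each; a single merged graph yields one group under its name)."""
    if schema is None:
        schema = default_schema()
    if isinstance(graphs, PropertyGraph):
        graphs = [graphs]
    report: dict[str, list[dict]] = {}
    for g in graphs:
        report[g.name or "graph"] = q1_fe_microbes(
            g, polarity="positive", significant=True, schema=schema
        )
    return report


def _path_query(
    graph: PropertyGraph,
    anchor: NodeConstraint,
    anchor_edge: EdgeConstraint,
    design_var: str,
    relaxed: bool,
    schema: OntologySchema | None,
) -> set[str]:
    """Shared core of query cases 4 and 5: ... → design ← group → microbe."""
    microbe_edge = (
        EdgeConstraint(
            "grp", "mic", category=("regulation", "treatment_effect"), direction="out"
        )
        if relaxed
        else EdgeConstraint("grp", "mic", relation="influence")
    )
    if relaxed and schema is None:
        schema = default_schema()
    pattern = QueryPattern(
        nodes=(
            anchor,
            NodeConstraint(design_var, entity_type="ExperimentDesign"),
            NodeConstraint("grp", entity_type="ExperimentGroup"),
            NodeConstraint("mic", entity_type="MicrobiotaName"),
        ),
        edges=(
            anchor_edge,
            EdgeConstraint("grp", design_var, relation="belong_to"),
            microbe_edge,
        ),
        projection=("mic",),
    )
    return set(match_pattern(graph, pattern, schema=schema).column("mic"))


def q4_additive_path(
    graph: PropertyGraph,
    additive_name: str,
    relaxed: bool = False,
    schema: OntologySchema | None = None,
) -> set[str]:
    """Microbes associated with a feed additive / fermentation product.

    Follows additive → experiment design (``belong_to``), experiment group →
    that design (``belong_to``), group → microbe (``influence``; with
    ``relaxed=True`` any regulation or treatment-effect relation).
    """
    return _path_query(
        graph,
        NodeConstraint("n1", name=additive_name),
        EdgeConstraint("n1", "m1", relation="belong_to"),
        "m1",
        relaxed,
        schema,
    )


def q5_breed_path(
    graph: PropertyGraph,
    breed_name: str,
    relaxed: bool = False,
    schema: OntologySchema | None = None,
) -> set[str]:
    """Microbes associated with a pig breed, through the experiment designs
    applied to that breed and their experiment groups."""
    return _path_query(
        graph,
        NodeConstraint("b", entity_type="SwineBreed", name=breed_name),
        EdgeConstraint("m1", "b", relation="belong_to"),
        "m1",
        relaxed,
        schema,
    )


# ---------------------------------------------------------------------------
# Cypher text emission / parsing (emitted subset)
# ---------------------------------------------------------------------------


def emit_cypher(pattern: QueryPattern) -> str:
    """Deterministic ``MATCH … return …`` text for a pattern.

    Only node-label / exact-name and relation-label constraints have a Cypher
    surface form; category/polarity/significance-filtered edges raise.  Each
    node is printed with its label and name at first occurrence, then by bare
    variable.
    """
    for ec in pattern.edges:
        if ec.category is not None or ec.polarity is not None or ec.significant is not None:
            raise PatternError(
                "metadata-filtered edges have no Cypher form; use match_pattern"
            )

    printed: set[str] = set()

    def node_text(var: str) -> str:
        if var in printed:
            return f"({var})"
        printed.add(var)
        nc = pattern.node(var)
        label = f":{nc.entity_type}" if nc.entity_type else ""
        name = f"{{name:'{nc.name}'}}" if nc.name is not None else ""
        return f"({var}{label}{name})"

    parts = []
    for i, ec in enumerate(pattern.edges, 1):
        rel = f"r{i}" + (f":{ec.relation}" if ec.relation else "")
        if ec.direction == "out":
            parts.append(f"{node_text(ec.src)}-[{rel}]->{node_text(ec.dst)}")
        else:
            parts.append(f"{node_text(ec.src)}<-[{rel}]-{node_text(ec.dst)}")
    for nc in pattern.nodes:
        if nc.var not in printed:
            parts.append(node_text(nc.var))
    return f"MATCH {', '.join(parts)} return {', '.join(pattern.projection)}"


_CY_NODE = re.compile(
    r"\((?P<var>\w+)(?::(?P<label>\w+))?(?:\{name:'(?P<name>[^']*)'\})?\)"
)


def parse_cypher_pattern(text: str) -> QueryPattern:
    """Parse the subset of Cypher emitted by :func:`emit_cypher`."""
    text = re.sub(r"\s*→\s*", "->", text.strip())  # tolerate typeset arrows
    m = re.match(r"^MATCH\s+(?P<body>.*?)\s+return\s+(?P<proj>.*)$", text, re.IGNORECASE | re.DOTALL)
    if not m:
        raise PatternError("not a MATCH ... return ... statement")
    body, proj = m.group("body"), m.group("proj")
    # edge variables (r1, r2, ...) in the return clause are dropped: results
    # project node bindings, edge provenance travels separately
    projection = tuple(
        v.strip()
        for v in proj.split(",")
        if v.strip() and not re.fullmatch(r"r\d+", v.strip())
    )
    # split on top-level commas between path segments
    segments = re.split(r"\)\s*,\s*\(", body)
    if len(segments) > 1:
        segments = [
            (s if s.startswith("(") else "(" + s) + ("" if s.endswith(")") else ")")
            for s in [seg for seg in segments]
        ]
    nodes: dict[str, NodeConstraint] = {}
    order: list[str] = []
    edges: list[EdgeConstraint] = []

    def register(var: str, label: str | None, name: str | None) -> None:
        if var not in nodes:
            nodes[var] = NodeConstraint(var, entity_type=label, name=name)
            order.append(var)

    for seg in segments:
        seg = seg.strip()
        pos = 0
        prev_var: str | None = None
        pending_rel: tuple[str | None, str] | None = None  # (relation, direction)
        while pos < len(seg):
            nm = _CY_NODE.match(seg, pos)
            if not nm:
                raise PatternError(f"unparseable pattern segment near {seg[pos:]!r}")
            var = nm.group("var")
            register(var, nm.group("label"), nm.group("name"))
            if prev_var is not None and pending_rel is not None:
                rel, direction = pending_rel
                edges.append(
                    EdgeConstraint(prev_var, var, relation=rel, direction=direction)
                )
            prev_var = var
            pos = nm.end()
            if pos >= len(seg):
                break
            em = re.match(
                r"(?P<back><)?-\[\w*(?::(?P<rel>\w+))?\]-(?P<fwd>>)?", seg[pos:]
            )
            if not em:
                raise PatternError(f"unparseable edge near {seg[pos:]!r}")
            rel = em.group("rel")
            if em.group("fwd"):
                pending_rel = (rel, "out")
            elif em.group("back"):
                pending_rel = (rel, "in")
            else:
                raise PatternError("undirected pattern edges are not supported")
            pos += em.end()
    return QueryPattern(
        nodes=tuple(nodes[v] for v in order),
        edges=tuple(edges),
        projection=projection,
    )


def parse_pattern_file(text: str) -> QueryPattern:
    """Parse the small declarative pattern format::

        node n1 FeedFermentationType name="fermented spent mushroom substrates"
        node m1 ExperimentDesign
        edge n1 belong_to m1
        return m1

    A type of ``*`` leaves the node unconstrained; ``edge a * b`` matches any
    relation; ``edge a <category:regulation,treatment_effect> b`` filters by
    relation category. Lines starting with ``#`` are comments.
    """
    nodes: list[NodeConstraint] = []
    edges: list[EdgeConstraint] = []
    projection: tuple[str, ...] = ()
    for lineno, raw in enumerate(text.splitlines(), 1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split(None, 1)
        kind = parts[0]
        rest = parts[1] if len(parts) > 1 else ""
        if kind == "node":
            m = re.match(r"^(\w+)\s+(\S+)(?:\s+name=\"(.*)\")?$", rest)
            if not m:
                raise PatternError(f"line {lineno}: bad node declaration")
            var, etype, name = m.groups()
            nodes.append(
                NodeConstraint(var, None if etype == "*" else etype, name)
            )
        elif kind == "edge":
            m = re.match(r"^(\w+)\s+(\S+)\s+(\w+)$", rest)
            if not m:
                raise PatternError(f"line {lineno}: bad edge declaration")
            src, rel, dst = m.groups()
            cm = re.match(r"^<category:([\w,]+)>$", rel)
            if cm:
                edges.append(
                    EdgeConstraint(src, dst, category=tuple(cm.group(1).split(",")))
                )
            elif rel == "*":
                edges.append(EdgeConstraint(src, dst))
            else:
                edges.append(EdgeConstraint(src, dst, relation=rel))
        elif kind == "return":
            projection = tuple(rest.split())
        else:
            raise PatternError(f"line {lineno}: unknown directive {kind!r}")
    if not nodes:
        raise PatternError("pattern file declares no nodes")
    return QueryPattern(tuple(nodes), tuple(edges), projection)
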