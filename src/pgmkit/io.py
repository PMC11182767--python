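"""Bit-exact exporters and importers for the property graph.

Three interchange formats, all text:

* **Cypher** script — MERGE statements for nodes, MATCH+CREATE for edges,
  with backtick-quoted identifiers and escaped single-quoted strings.  The
  importer parses exactly the dialect the exporter emits.
* **Neo4j bulk-import CSV** — one node file (``:ID,name,:LABEL``) and one
  relationship file (``:START_ID,:END_ID,:TYPE,source`` plus one column per
  edge-attribute key), RFC-4180 quoting, UTF-8.
* **GraphML** — via networkx, with edge attributes flattened under an ``a_``
  prefix.

All exporters write nodes and edges in sorted key order, so output is
deterministic for a given graph, and export→import round-trips to an equal
graph.
"""

from __future__ import annotations

import csv
import io as _io
import re
from pathlib import Path

import networkx as nx

from .graph import NodeKey, PropertyGraph, Triple

__all__ = [
    "export_cypher",
    "import_cypher",
    "export_neo4j_csv",
    "import_neo4j_csv",
    "export_graphml",
    "import_graphml",
    "save_graph",
    "load_graph",
]

_ATTR_PREFIX = "a_"


def _node_ids(graph: PropertyGraph) -> dict[NodeKey, str]:
    return {key: f"n{i}" for i, key in enumerate(graph.node_keys())}


# ---------------------------------------------------------------------------
# Cypher
# ---------------------------------------------------------------------------


def _q_ident(s: str) -> str:
    return "`" + s.replace("`", "``") + "`"


def _q_str(s: str) -> str:
    return "'" + s.replace("\\", "\\\\").replace("'", "\\'") + "'"


def export_cypher(graph: PropertyGraph) -> str:
    """Cypher script recreating the graph (MERGE nodes, CREATE relationships)."""
    lines = [f"// knowledge base: {graph.name}"]
    for key, display in graph.nodes():
        lines.append(
            f"MERGE (:{_q_ident(key.entity_type)} {{`name`: {_q_str(display)}}});"
        )
    for t in graph.triples():
        props = [f"`source`: {_q_str(t.source)}"]
        for k, v in t.attributes:
            props.append(f"{_q_ident(k)}: {_q_str(v)}")
        lines.append(
            "MATCH "
            f"(a:{_q_ident(t.subject_type)} {{`name`: {_q_str(t.subject)}}}), "
            f"(b:{_q_ident(t.object_type)} {{`name`: {_q_str(t.object)}}}) "
            f"CREATE (a)-[:{_q_ident(t.relation)} {{{', '.join(props)}}}]->(b);"
        )
    return "\n".join(lines) + "\n"


_IDENT = r"`((?:[^`]|``)*)`"
_STR = r"'((?:[^'\\]|\\.)*)'"
_NODE_RE = re.compile(rf"^MERGE \(:{_IDENT} \{{`name`: {_STR}\}}\);$")
_EDGE_RE = re.compile(
    rf"^MATCH \(a:{_IDENT} \{{`name`: {_STR}\}}\), "
    rf"\(b:{_IDENT} \{{`name`: {_STR}\}}\) "
    rf"CREATE \(a\)-\[:{_IDENT} \{{(.*)\}}\]->\(b\);$"
)
_PROP_RE = re.compile(rf"{_IDENT}: {_STR}")


def _unq_ident(s: str) -> str:
    return s.replace("``", "`")


def _unq_str(s: str) -> str:
    return re.sub(r"\\(.)", r"\1", s)


def import_cypher(text: str) -> PropertyGraph:
    """Parse a script produced by :func:`export_cypher` back into a graph."""
    name = ""
    graph = PropertyGraph()
    for lineno, line in enumerate(text.splitlines(), 1):
        line = line.strip()
        if not line:
            continue
        if line.startswith("//"):
            m = re.match(r"^// knowledge base: (.*)$", line)
            if m:
                name = m.group(1)
            continue
        m = _NODE_RE.match(line)
        if m:
            graph.add_node(_unq_str(m.group(2)), _unq_ident(m.group(1)))
            continue
        m = _EDGE_RE.match(line)
        if m:
            s_type, s_name, o_type, o_name, rel, props_text = m.groups()
            props = {
                _unq_ident(k): _unq_str(v) for k, v in _PROP_RE.findall(props_text)
            }
            source = props.pop("source", "unknown")
            graph.add_triple(
                Triple(
                    subject=_unq_str(s_name),
                    subject_type=_unq_ident(s_type),
                    relation=_unq_ident(rel),
                    object=_unq_str(o_name),
                    object_type=_unq_ident(o_type),
                    source=source,
                    attributes=tuple(sorted(props.items())),
                )
            )
            continue
        raise ValueError(f"unparseable Cypher at line {lineno}: {line!r}")
    graph.name = name
    return graph


# ---------------------------------------------------------------------------
# Neo4j bulk-import CSV
# ---------------------------------------------------------------------------


def export_neo4j_csv(graph: PropertyGraph) -> tuple[str, str]:
    """(nodes file, relationships file) as CSV text."""
    ids = _node_ids(graph)
    nodes_buf = _io.StringIO()
    w = csv.writer(nodes_buf, lineterminator="\n")
    w.writerow([":ID", "name", ":LABEL"])
    for key, display in graph.nodes():
        w.writerow([ids[key], display, key.entity_type])

    attr_keys = sorted({k for t in graph.triples() for k, _ in t.attributes})
    rels_buf = _io.StringIO()
    w = csv.writer(rels_buf, lineterminator="\n")
    w.writerow([":START_ID", ":END_ID", ":TYPE", "source"] + attr_keys)
    for t in graph.triples():
        amap = t.attribute_map
        w.writerow(
            [ids[t.subject_key], ids[t.object_key], t.relation, t.source]
            + [amap.get(k, "") for k in attr_keys]
        )
    return nodes_buf.getvalue(), rels_buf.getvalue()


def import_neo4j_csv(nodes_text: str, rels_text: str, name: str = "") -> PropertyGraph:
    graph = PropertyGraph(name)
    by_id: dict[str, tuple[str, str]] = {}
    reader = csv.reader(_io.StringIO(nodes_text))
    header = next(reader)
    if header[:3] != [":ID", "name", ":LABEL"]:
        raise ValueError(f"unexpected node-file header: {header!r}")
    for row in reader:
        nid, display, label = row[0], row[1], row[2]
        by_id[nid] = (display, label)
        graph.add_node(display, label)
    reader = csv.reader(_io.StringIO(rels_text))
    header = next(reader)
    if header[:4] != [":START_ID", ":END_ID", ":TYPE", "source"]:
        raise ValueError(f"unexpected relationship-file header: {header!r}")
    attr_keys = header[4:]
    for row in reader:
        s_name, s_type = by_id[row[0]]
        o_name, o_type = by_id[row[1]]
        attrs = {k: v for k, v in zip(attr_keys, row[4:]) if v != ""}
        graph.add_triple(
            Triple(
                subject=s_name,
                subject_type=s_type,
                relation=row[2],
                object=o_name,
                object_type=o_type,
                source=row[3],
                attributes=tuple(sorted(attrs.items())),
            )
        )
    return graph


# ---------------------------------------------------------------------------
# GraphML
# ---------------------------------------------------------------------------


def export_graphml(graph: PropertyGraph) -> str:
    g = nx.MultiDiGraph(kb_name=graph.name)
    ids = _node_ids(graph)
    for key, display in graph.nodes():
        g.add_node(ids[key], name=display, entity_type=key.entity_type)
    for i, t in enumerate(graph.triples()):
        data = {"relation": t.relation, "source": t.source}
        for k, v in t.attributes:
            data[_ATTR_PREFIX + k] = v
        g.add_edge(ids[t.subject_key], ids[t.object_key], key=str(i), **data)
    return "\n".join(nx.generate_graphml(g, named_key_ids=True)) + "\n"


def import_graphml(text: str) -> PropertyGraph:
    g = nx.parse_graphml(text, force_multigraph=True)
    graph = PropertyGraph(g.graph.get("kb_name", ""))
    info = {}
    for nid, data in g.nodes(data=True):
        info[nid] = (data["name"], data["entity_type"])
        graph.add_node(data["name"], data["entity_type"])
    for u, v, data in g.edges(data=True):
        attrs = {
            k[len(_ATTR_PREFIX):]: val
            for k, val in data.items()
            if k.startswith(_ATTR_PREFIX)
        }
        s_name, s_type = info[u]
        o_name, o_type = info[v]
        graph.add_triple(
            Triple(
                subject=s_name,
                subject_type=s_type,
                relation=data["relation"],
                object=o_name,
                object_type=o_type,
                source=data.get("source", "unknown"),
                attributes=tuple(sorted(attrs.items())),
            )
        )
    return graph


# ---------------------------------------------------------------------------
# file-level helpers (format by extension)
# ---------------------------------------------------------------------------


def save_graph(graph: PropertyGraph, path: str | Path, fmt: str | None = None) -> list[Path]:
    """Write a graph to disk; format from ``fmt`` or the file extension.

    ``neo4j-csv`` writes ``<stem>.nodes.csv`` and ``<stem>.relationships.csv``.
    Returns the paths written.
    """
    path = Path(path)
    fmt = fmt or {".graphml": "graphml", ".cypher": "cypher", ".csv": "neo4j-csv"}.get(
        path.suffix, "graphml"
    )
    if fmt == "graphml":
        path.write_text(export_graphml(graph), encoding="utf-8")
        return [path]
    if fmt == "cypher":
        path.write_text(export_cypher(graph), encoding="utf-8")
        return [path]
    if fmt == "neo4j-csv":
        stem = path.with_suffix("") if path.suffix == ".csv" else path
        nodes_text, rels_text = export_neo4j_csv(graph)
        n_path = Path(str(stem) + ".nodes.csv")
        r_path = Path(str(stem) + ".relationships.csv")
        n_path.write_text(nodes_text, encoding="utf-8")
        r_path.write_text(rels_text, encoding="utf-8")
        return [n_path, r_path]
    raise ValueError(f"unknown graph format: {fmt!r}")


def load_graph(path: str | Path) -> PropertyGraph:
    path = Path(path)
    if path.name.endswith(".nodes.csv") or path.name.endswith(".relationships.csv"):
        stem = str(path).rsplit(".", 3)[0]
        nodes = Path(stem + ".nodes.csv").read_text(encoding="utf-8")
        rels = Path(stem + ".relationships.csv").read_text(encoding="utf-8")
        return import_neo4j_csv(nodes, rels)
    text = path.read_text(encoding="utf-8")
    if path.suffix == ".cypher":
        return import_cypher(text)
    return import_graphml(text)
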