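"""Ingest curated literature annotations (the pgmReading knowledge base).

Two input shapes are supported:

* annotation exports — JSON documents whose records carry a ``Triple_list``
  payload ``{"relation", "object_type", "subject_type", "object", "subject"}``,
  optionally wrapped with a ``PMID``;
* feed-efficiency association tables — TSV with columns Taxonomy, PMID,
  MicrobiotaName, Relation, Phenotype (one row per literature assertion).

Records that fail ontology validation are collected into a rejects report
with their positions, never silently dropped.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import IO, Iterable, Mapping

import pandas as pd

from .graph import IngestReport, PropertyGraph, Triple, name_key
from .ontology import OntologySchema, default_schema

__all__ = [
    "parse_annotation_export",
    "load_fe_association_table",
    "REQUIRED_TABLE_COLUMNS",
]

REQUIRED_TABLE_COLUMNS = ("Taxonomy", "PMID", "MicrobiotaName", "Relation", "Phenotype")

_TRIPLE_FIELDS = ("relation", "object_type", "subject_type", "object", "subject")


def _iter_records(doc) -> Iterable[tuple[int, str, Mapping]]:
    """Yield (position, pmid, flat triple record) from an annotation export."""
    if isinstance(doc, Mapping):
        doc = [doc]
    for i, entry in enumerate(doc):
        if not isinstance(entry, Mapping):
            raise ValueError(f"record {i}: expected an object, got {type(entry).__name__}")
        pmid = str(entry.get("PMID", entry.get("pmid", "unknown")) or "unknown")
        payload = entry.get("Triple_list", entry)
        records = payload if isinstance(payload, list) else [payload]
        for rec in records:
            yield i, pmid, rec


def parse_annotation_export(
    doc: str | Path | IO[str] | list | Mapping,
    schema: OntologySchema | None = None,
) -> tuple[list[Triple], IngestReport]:
    """Parse an annotation export into schema-valid triples plus a rejects report.

    ``doc`` may be a JSON file path, an open stream, JSON text, or the
    already-decoded structure. Entity types are normalized through the
    schema's alias rules (``Swine_Breed`` -> ``SwineBreed``).
    """
    if schema is None:
        schema = default_schema()
    if isinstance(doc, Path):
        doc = doc.read_text(encoding="utf-8")
    elif hasattr(doc, "read"):
        doc = doc.read()
    if isinstance(doc, str):
        p = Path(doc)
        if doc and "\n" not in doc and not doc.lstrip().startswith(("[", "{")) and p.is_file():
            doc = p.read_text(encoding="utf-8")
        try:
            doc = json.loads(doc)
        except json.JSONDecodeError as exc:
            raise ValueError(
                f"malformed annotation export at line {exc.lineno}, column {exc.colno}: "
                f"{exc.msg}"
            ) from exc

    triples: list[Triple] = []
    report = IngestReport()
    for pos, pmid, rec in _iter_records(doc):
        if not isinstance(rec, Mapping):
            report.reject(pos, None, "triple record is not an object")
            continue
        missing = [f for f in _TRIPLE_FIELDS if f not in rec]
        if missing:
            report.reject(pos, None, f"missing fields: {', '.join(missing)}")
            continue
        try:
            t = Triple(
                subject=str(rec["subject"]),
                subject_type=str(rec["subject_type"]),
                relation=str(rec["relation"]),
                object=str(rec["object"]),
                object_type=str(rec["object_type"]),
                source=pmid,
            )
        except ValueError as exc:
            report.reject(pos, None, str(exc))
            continue
        reason = t.validate(schema)
        if reason is not None:
            report.reject(pos, t, reason)
            continue
        # canonicalize entity-type spellings to the schema's forms
        t = Triple(
            subject=t.subject,
            subject_type=schema.canonical_detail_type(t.subject_type),
            relation=t.relation,
            object=t.object,
            object_type=schema.canonical_detail_type(t.object_type),
            source=t.source,
            attributes=t.attributes,
        )
        triples.append(t)
        report.added += 1
    return triples, report


def load_fe_association_table(
    rows: str | Path | pd.DataFrame,
    schema: OntologySchema | None = None,
    empty_relation: str = "correlated_with",
    name: str = "pgmReading",
) -> tuple[PropertyGraph, IngestReport]:
    """Build the curated feed-efficiency graph from an association table.

    Per row emits ``(MicrobiotaName, Relation, <Phenotype>)`` with the row's
    PMID as provenance, plus one ``(MicrobiotaName, belong_to, Taxonomy)``
    structural edge per distinct (microbe, taxonomy) pair.  Rows with an empty
    Relation cell get ``empty_relation`` and are flagged with a
    ``relation_imputed`` edge attribute (the source table leaves their
    relation cell blank without stating why).
    """
    if schema is None:
        schema = default_schema()
    if not isinstance(rows, pd.DataFrame):
        rows = pd.read_csv(rows, sep="\t", dtype=str, keep_default_na=False)
    for col in REQUIRED_TABLE_COLUMNS:
        if col not in rows.columns:
            raise ValueError(f"association table is missing required column {col!r}")

    graph = PropertyGraph(name)
    report = IngestReport()
    seen_taxonomy: set[tuple[str, str]] = set()
    for _, row in rows.iterrows():
        microbe = str(row["MicrobiotaName"]).strip()
        if not microbe:
            report.reject(None, None, "row with empty MicrobiotaName")
            continue
        pmid = str(row["PMID"]).strip() or "unknown"
        relation = str(row["Relation"]).strip()
        attributes: tuple[tuple[str, str], ...] = ()
        if not relation:
            relation = empty_relation
            attributes = (("relation_imputed", "true"),)
        phenotype = str(row["Phenotype"]).strip()
        graph.add_triple(
            Triple(
                subject=microbe,
                subject_type="MicrobiotaName",
                relation=relation,
                object=phenotype,
                object_type="FeedEfficiency",
                source=pmid,
                attributes=attributes,
            ),
            schema=schema,
            report=report,
        )
        taxonomy = str(row["Taxonomy"]).strip()
        if taxonomy:
            pair = (name_key(microbe), name_key(taxonomy))
            if pair not in seen_taxonomy:
                seen_taxonomy.add(pair)
                graph.add_triple(
                    Triple(
                        subject=microbe,
                        subject_type="MicrobiotaName",
                        relation="belong_to",
                        object=taxonomy,
                        object_type="MicrobiotaTaxonomy",
                        source=pmid,
                    ),
                    schema=schema,
                    report=report,
                )
    return graph, report
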