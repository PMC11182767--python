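"""Map structured association databases onto ontology triples (pgmDatabase).

Three table shapes are covered:

* microbe–phenotype association tables (ADDAGMA-shaped): per record, a
  ``belong_to`` edge to the taxonomic rank, a ``correlated_with`` edge to the
  phenotype node carrying the evidence (condition, P-value, mean relative
  abundances) as edge attributes, and a ``located_in`` edge when a sampling
  site is given;
* microbe → metabolite tables (gutMGene-shaped): one ``produce`` edge per
  distinct pair;
* metabolite → pathway tables (KEGG compound→pathway): one ``involved_in``
  edge per distinct pair.

Column names of a concrete source file are adapted through a declarative
column map (YAML sidecar); three maps matching the shipped fixtures are
packaged under ``pgmkit/data/colmap_*.yaml``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
import yaml

from .graph import Triple, name_key

__all__ = [
    "AssociationRecord",
    "map_phenotype_table",
    "map_metabolite_table",
    "map_pathway_table",
    "read_association_table",
    "read_pair_table",
    "load_column_map",
]


@dataclass(frozen=True)
class AssociationRecord:
    """One structured microbe–phenotype association row, pre-mapping."""

    microbe: str
    taxonomy_rank: str = ""
    phenotype: str = "Feed efficiency"
    condition: str = ""
    p_value: float | None = None
    mean_ra_case: float | None = None
    mean_ra_control: float | None = None
    sampling_site: str = ""

    def __post_init__(self):
        if self.p_value is not None and not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p_value out of [0, 1]: {self.p_value}")


def map_phenotype_table(
    records: Iterable[AssociationRecord], source: str = "ADDAGMA"
) -> tuple[list[Triple], list[tuple[int, str]]]:
    """Triples from association records; records lacking a microbe name are
    returned as (position, reason) rejects.

    The evidence attributes (Condition, Pvalue, Mean(RA)_case/control) travel
    on the ``correlated_with`` edge, so each condition contributes its own
    edge; the structural ``belong_to``/``located_in`` edges are emitted once
    per distinct pair.
    """
    triples: list[Triple] = []
    rejects: list[tuple[int, str]] = []
    seen_taxonomy: set[tuple[str, str]] = set()
    seen_site: set[tuple[str, str]] = set()
    for i, rec in enumerate(records):
        if not rec.microbe.strip():
            rejects.append((i, "record missing microbe name"))
            continue
        attrs: dict[str, str] = {}
        if rec.condition:
            attrs["Condition"] = rec.condition
        if rec.p_value is not None:
            attrs["Pvalue"] = repr(rec.p_value)
        if rec.mean_ra_case is not None:
            attrs["Mean(RA)_case"] = repr(rec.mean_ra_case)
        if rec.mean_ra_control is not None:
            attrs["Mean(RA)_control"] = repr(rec.mean_ra_control)
        triples.append(
            Triple(
                subject=rec.microbe,
                subject_type="MicrobiotaName",
                relation="correlated_with",
                object=rec.phenotype,
                object_type="FeedEfficiency",
                source=source,
                attributes=tuple(sorted(attrs.items())),
            )
        )
        if rec.taxonomy_rank:
            pair = (name_key(rec.microbe), name_key(rec.taxonomy_rank))
            if pair not in seen_taxonomy:
                seen_taxonomy.add(pair)
                triples.append(
                    Triple(
                        subject=rec.microbe,
                        subject_type="MicrobiotaName",
                        relation="belong_to",
                        object=rec.taxonomy_rank,
                        object_type="MicrobiotaTaxonomy",
                        source=source,
                    )
                )
        if rec.sampling_site:
            pair = (name_key(rec.microbe), name_key(rec.sampling_site))
            if pair not in seen_site:
                seen_site.add(pair)
                triples.append(
                    Triple(
                        subject=rec.microbe,
                        subject_type="MicrobiotaName",
                        relation="located_in",
                        object=rec.sampling_site,
                        object_type="SamplingSites",
                        source=source,
                    )
                )
    return triples, rejects


def _distinct_pair_triples(
    rows: Iterable[tuple[str, str]],
    relation: str,
    subject_type: str,
    object_type: str,
    source: str,
) -> list[Triple]:
    triples: list[Triple] = []
    seen: set[tuple[str, str]] = set()
    for subj, obj in rows:
        if not str(subj).strip() or not str(obj).strip():
            continue
        pair = (name_key(str(subj)), name_key(str(obj)))
        if pair in seen:
            continue
        seen.add(pair)
        triples.append(
            Triple(
                subject=str(subj),
                subject_type=subject_type,
                relation=relation,
                object=str(obj),
                object_type=object_type,
                source=source,
            )
        )
    return triples


def map_metabolite_table(
    rows: Iterable[tuple[str, str]], source: str = "gutMGene"
) -> list[Triple]:
    """One ``(microbe, produce, metabolite)`` triple per distinct pair."""
    return _distinct_pair_triples(
        rows, "produce", "MicrobiotaName", "MetabolitesName", source
    )


def map_pathway_table(
    rows: Iterable[tuple[str, str]], source: str = "KEGG"
) -> list[Triple]:
    """One ``(metabolite, involved_in, pathway)`` triple per distinct pair."""
    return _distinct_pair_triples(
        rows, "involved_in", "MetabolitesName", "MetabolismName", source
    )


# ---------------------------------------------------------------------------
# column-mapped readers
# ---------------------------------------------------------------------------


def load_column_map(spec: str | Path | Mapping) -> dict[str, str]:
    """Load a column map: our field name -> source column name."""
    if isinstance(spec, Mapping):
        doc = dict(spec)
    else:
        doc = yaml.safe_load(Path(spec).read_text(encoding="utf-8"))
    columns = doc.get("columns", doc)
    if not isinstance(columns, Mapping):
        raise ValueError("column map must contain a 'columns' mapping")
    return {str(k): str(v) for k, v in columns.items()}


def _opt_float(value: str) -> float | None:
    value = str(value).strip()
    if value in ("", "NA", "nan", "None"):
        return None
    return float(value)


def read_association_table(
    path: str | Path | pd.DataFrame, column_map: Mapping[str, str] | str | Path
) -> list[AssociationRecord]:
    """Read an ADDAGMA-shaped TSV through a column map into records."""
    cmap = load_column_map(column_map) if not isinstance(column_map, Mapping) else dict(column_map)
    if not isinstance(path, pd.DataFrame):
        path = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if "microbe" not in cmap:
        raise ValueError("column map must define at least 'microbe'")
    missing = [src for src in cmap.values() if src not in path.columns]
    if missing:
        raise ValueError(f"source table is missing mapped column(s): {missing}")
    records = []
    for _, row in path.iterrows():
        get = lambda field: str(row[cmap[field]]).strip() if field in cmap else ""
        records.append(
            AssociationRecord(
                microbe=get("microbe"),
                taxonomy_rank=get("taxonomy_rank"),
                phenotype=get("phenotype") or "Feed efficiency",
                condition=get("condition"),
                p_value=_opt_float(get("p_value")) if "p_value" in cmap else None,
                mean_ra_case=_opt_float(get("mean_ra_case")) if "mean_ra_case" in cmap else None,
                mean_ra_control=(
                    _opt_float(get("mean_ra_control")) if "mean_ra_control" in cmap else None
                ),
                sampling_site=get("sampling_site"),
            )
        )
    return records


def read_pair_table(
    path: str | Path | pd.DataFrame,
    column_map: Mapping[str, str] | str | Path,
    subject_field: str = "subject",
    object_field: str = "object",
) -> list[tuple[str, str]]:
    """Read a two-column (subject, object) table through a column map."""
    cmap = load_column_map(column_map) if not isinstance(column_map, Mapping) else dict(column_map)
    if not isinstance(path, pd.DataFrame):
        path = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for field in (subject_field, object_field):
        if field not in cmap:
            raise ValueError(f"column map must define {field!r}")
        if cmap[field] not in path.columns:
            raise ValueError(f"source table is missing mapped column {cmap[field]!r}")
    return [
        (str(row[cmap[subject_field]]), str(row[cmap[object_field]]))
        for _, row in path.iterrows()
    ]
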