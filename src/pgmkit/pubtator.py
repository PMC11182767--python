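"""PubTator-format parsing and microbe-mention triple extraction.

The PubTator plain-text format carries one document per block::

    PMID|t|Title text
    PMID|a|Abstract text
    PMID<TAB>start<TAB>end<TAB>mention<TAB>type<TAB>concept_id
    ...
    <blank line>

Offsets are 0-based into the concatenation ``title + " " + abstract``.
Species mentions are reduced to two triples each,
``(MicrobiotaName, hasSource, PMID)`` and
``(MicrobiotaName, hasID, <concept id>)``, deduplicated per
(mention, pmid) and (mention, concept id) pair.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable

from .graph import Triple

__all__ = [
    "PubtatorAnnotation",
    "PubtatorDocument",
    "parse_pubtator",
    "serialize_pubtator",
    "extract_microbe_triples",
    "PubtatorParseError",
]


class PubtatorParseError(ValueError):
    pass


@dataclass(frozen=True)
class PubtatorAnnotation:
    pmid: str
    start: int
    end: int
    mention: str
    mention_type: str  # Gene / Disease / Chemical / Mutation / Species / ...
    concept_id: str

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid offsets [{self.start}, {self.end})")


@dataclass
class PubtatorDocument:
    pmid: str
    title: str
    abstract: str = ""
    annotations: list[PubtatorAnnotation] = field(default_factory=list)

    @property
    def text(self) -> str:
        return self.title + (" " + self.abstract if self.abstract else "")


def parse_pubtator(
    stream: str | Path | IO[str],
) -> tuple[list[PubtatorDocument], list[tuple[int, str]]]:
    """Parse PubTator text into documents; malformed annotation lines are
    returned as (line number, reason) rejects rather than raised.

    A document whose block lacks the ``|t|`` title line is a hard error
    (:class:`PubtatorParseError`).
    """
    if isinstance(stream, Path):
        text = stream.read_text(encoding="utf-8")
    elif isinstance(stream, str):
        p = Path(stream)
        if stream and "\n" not in stream and "|" not in stream and p.is_file():
            text = p.read_text(encoding="utf-8")
        else:
            text = stream
    else:
        text = stream.read()

    docs: list[PubtatorDocument] = []
    rejects: list[tuple[int, str]] = []
    current: PubtatorDocument | None = None
    for lineno, raw in enumerate(text.splitlines(), 1):
        line = raw.rstrip("\n")
        if not line.strip():
            current = None
            continue
        if "|t|" in line and "\t" not in line.split("|t|", 1)[0]:
            pmid, title = line.split("|t|", 1)
            current = PubtatorDocument(pmid=pmid, title=title)
            docs.append(current)
            continue
        if "|a|" in line and "\t" not in line.split("|a|", 1)[0]:
            pmid, abstract = line.split("|a|", 1)
            if current is None or current.pmid != pmid:
                raise PubtatorParseError(
                    f"line {lineno}: abstract for {pmid!r} without a preceding title line"
                )
            current.abstract = abstract
            continue
        fields = line.split("\t")
        if current is None:
            raise PubtatorParseError(
                f"line {lineno}: annotation line before any title line"
            )
        if len(fields) != 6:
            rejects.append((lineno, f"expected 6 tab-separated fields, got {len(fields)}"))
            continue
        pmid, start_s, end_s, mention, mtype, concept = fields
        try:
            ann = PubtatorAnnotation(
                pmid=pmid,
                start=int(start_s),
                end=int(end_s),
                mention=mention,
                mention_type=mtype,
                concept_id=concept,
            )
        except ValueError as exc:
            rejects.append((lineno, str(exc)))
            continue
        current.annotations.append(ann)
    return docs, rejects


def serialize_pubtator(docs: Iterable[PubtatorDocument]) -> str:
    """Inverse of :func:`parse_pubtator` on well-formed documents."""
    blocks = []
    for doc in docs:
        lines = [f"{doc.pmid}|t|{doc.title}"]
        if doc.abstract:
            lines.append(f"{doc.pmid}|a|{doc.abstract}")
        for a in doc.annotations:
            lines.append(
                "\t".join(
                    [a.pmid, str(a.start), str(a.end), a.mention, a.mention_type, a.concept_id]
                )
            )
        blocks.append("\n".join(lines))
    return "\n\n".join(blocks) + ("\n" if blocks else "")


def extract_microbe_triples(
    docs: Iterable[PubtatorDocument],
    keep_types: frozenset[str] | set[str] = frozenset({"Species"}),
    strict_literal: bool = False,
) -> list[Triple]:
    """Reduce parsed documents to microbe-mention triples.

    Per kept annotation: ``(mention, hasSource, PMID)`` and
    ``(mention, hasID, concept_id)``, deduplicated per (mention, pmid) and
    (mention, concept_id).  ``strict_literal=True`` points hasID at the PMID
    instead of the concept identifier (the literal form some pipelines state,
    at odds with the concept-identifier intent); the default keeps the
    concept identifier.
    """
    keep = frozenset(keep_types)
    triples: list[Triple] = []
    seen_source: set[tuple[str, str]] = set()
    seen_id: set[tuple[str, str]] = set()
    for doc in docs:
        for a in doc.annotations:
            if a.mention_type not in keep or not a.mention.strip():
                continue
            if (a.mention, a.pmid) not in seen_source:
                seen_source.add((a.mention, a.pmid))
                triples.append(
                    Triple(
                        subject=a.mention,
                        subject_type="MicrobiotaName",
                        relation="hasSource",
                        object=a.pmid,
                        object_type="PMID",
                        source=a.pmid,
                    )
                )
            id_object = a.pmid if strict_literal else a.concept_id
            id_type = "PMID" if strict_literal else "ConceptID"
            if id_object.strip() and (a.mention, id_object) not in seen_id:
                seen_id.add((a.mention, id_object))
                triples.append(
                    Triple(
                        subject=a.mention,
                        subject_type="MicrobiotaName",
                        relation="hasID",
                        object=id_object,
                        object_type=id_type,
                        source=a.pmid,
                    )
                )
    return triples
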