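"""Domain ontology for the pig-gut-microbiota knowledge graph.

The ontology is a closed schema: 11 entity classes, each carrying a set of
*detail types* (the node labels actually used in the graph, e.g.
``MicrobiotaName``, ``FeedEfficiency``), and a fixed relation vocabulary
grouped into six categories (``sameAs``, ``hasProperty``, ``subClassOf``,
``regulation``, ``treatment_effect``, ``comparison``).

Relation labels additionally carry a *polarity* (positive / negative /
neutral) and a *significance* flag.  Labels prefixed ``significantly_`` and
the four regulation labels (``increase``/``decrease``/``upregulate``/
``downregulate``) denote associations reported at P < 0.05 in their source
and are therefore marked significant.

Lookups are deliberately strict: an unknown relation label raises
:class:`UnknownRelationError` rather than being silently classified.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import IO, Iterable, Mapping

import yaml

__all__ = [
    "RelationMeta",
    "OntologySchema",
    "SchemaError",
    "UnknownRelationError",
    "ValidationResult",
    "load_schema",
    "default_schema",
    "canonical_relation",
    "canonical_type_key",
    "POSITIVE_RELATIONS",
    "NEGATIVE_RELATIONS",
    "CATEGORIES",
]

CATEGORIES = (
    "sameAs",
    "hasProperty",
    "subClassOf",
    "regulation",
    "treatment_effect",
    "comparison",
)

#: relation labels (canonical form) that assert a positive association
POSITIVE_RELATIONS = frozenset(
    {
        "positively_correlated_with",
        "significantly_positively_correlated",
        "increase",
        "upregulate",
        "higher",
        "highest",
        "significantly_higher",
        "heavier",
    }
)

#: relation labels (canonical form) that assert a negative association
NEGATIVE_RELATIONS = frozenset(
    {
        "negatively_correlated_with",
        "significantly_negatively_correlated",
        "decrease",
        "downregulate",
        "inhibite",
        "lower",
        "lowest",
    }
)

_SIGNIFICANT_EXACT = frozenset({"increase", "decrease", "upregulate", "downregulate"})


class SchemaError(ValueError):
    """Malformed or inconsistent ontology document."""


class UnknownRelationError(KeyError):
    """Relation label not in the schema vocabulary."""

    def __init__(self, label: str):
        super().__init__(label)
        self.label = label

    def __str__(self) -> str:  # KeyError quotes its arg; keep the message readable
        return f"unknown relation label: {self.label!r}"


def canonical_relation(label: str) -> str:
    """Canonical form of a relation label: trimmed, spaces→underscores, casefolded.

    The source tables mix capitalizations (``Positively_correlated_with`` vs
    ``positively_correlated_with``); matching is case-insensitive.
    """
    return re.sub(r"\s+", "_", label.strip()).casefold()


def canonical_type_key(entity_type: str) -> str:
    """Matching key for an entity/detail type: underscores removed, casefolded.

    Annotation exports write ``Swine_Breed`` where the schema says
    ``SwineBreed``; both normalize to the same key.
    """
    return entity_type.strip().replace("_", "").casefold()


def _relation_polarity(canonical: str) -> str:
    if canonical in POSITIVE_RELATIONS:
        return "positive"
    if canonical in NEGATIVE_RELATIONS:
        return "negative"
    return "neutral"


def _relation_significant(canonical: str) -> bool:
    return canonical.startswith("significantly_") or canonical in _SIGNIFICANT_EXACT


@dataclass(frozen=True)
class RelationMeta:
    """Metadata attached to one relation label."""

    label: str  # canonical form
    category: str
    polarity: str  # positive | negative | neutral
    significant: bool


@dataclass(frozen=True)
class ValidationResult:
    accepted: bool
    reason: str = ""
    canonical_type: str | None = None

    def __bool__(self) -> bool:
        return self.accepted


class OntologySchema:
    """Closed vocabulary of entity classes, detail types and relation labels.

    Parameters
    ----------
    classes
        Mapping class name -> iterable of detail-type names. A detail type may
        belong to exactly one class.
    relations
        Mapping category -> iterable of relation labels.
    name
        Optional schema name, preserved through serialization.
    """

    def __init__(
        self,
        classes: Mapping[str, Iterable[str]],
        relations: Mapping[str, Iterable[str]],
        name: str = "",
    ):
        self.name = name
        self._classes: dict[str, tuple[str, ...]] = {}
        self._type_class: dict[str, str] = {}  # canonical type key -> class
        self._type_canonical: dict[str, str] = {}  # canonical type key -> display form
        for cls, dts in classes.items():
            dts = tuple(dts)
            self._classes[cls] = dts
            for dt in dts:
                key = canonical_type_key(dt)
                if key in self._type_class:
                    raise SchemaError(
                        f"detail type {dt!r} declared under both "
                        f"{self._type_class[key]!r} and {cls!r}"
                    )
                self._type_class[key] = cls
                self._type_canonical[key] = dt
        self._relations: dict[str, RelationMeta] = {}
        self._relation_category_order: dict[str, tuple[str, ...]] = {}
        for category, labels in relations.items():
            if category not in CATEGORIES:
                raise SchemaError(f"unknown relation category: {category!r}")
            labels = tuple(labels)
            self._relation_category_order[category] = labels
            for label in labels:
                canon = canonical_relation(label)
                if canon in self._relations:
                    raise SchemaError(f"relation {label!r} declared twice")
                self._relations[canon] = RelationMeta(
                    label=canon,
                    category=category,
                    polarity=_relation_polarity(canon),
                    significant=_relation_significant(canon),
                )

    # -- introspection -------------------------------------------------------

    @property
    def classes(self) -> frozenset[str]:
        return frozenset(self._classes)

    @property
    def detail_types(self) -> frozenset[str]:
        return frozenset(self._type_canonical.values())

    @property
    def relations(self) -> dict[str, RelationMeta]:
        return dict(self._relations)

    def detail_types_of(self, cls: str) -> tuple[str, ...]:
        return self._classes[cls]

    def class_of(self, detail_type: str) -> str:
        return self._type_class[canonical_type_key(detail_type)]

    def has_detail_type(self, entity_type: str) -> bool:
        return canonical_type_key(entity_type) in self._type_canonical

    def canonical_detail_type(self, entity_type: str) -> str:
        """Schema spelling of an entity type (``Swine_Breed`` -> ``SwineBreed``)."""
        try:
            return self._type_canonical[canonical_type_key(entity_type)]
        except KeyError:
            raise SchemaError(f"unknown entity type: {entity_type!r}") from None

    def has_relation(self, label: str) -> bool:
        return canonical_relation(label) in self._relations

    def relation(self, label: str) -> RelationMeta:
        try:
            return self._relations[canonical_relation(label)]
        except KeyError:
            raise UnknownRelationError(label) from None

    # -- extension (used by the literature-mention ingester) -----------------

    def register_detail_type(self, cls: str, detail_type: str) -> None:
        """Add a detail type (creating the class if needed)."""
        key = canonical_type_key(detail_type)
        if key in self._type_class:
            return
        self._classes.setdefault(cls, ())
        self._classes[cls] = self._classes[cls] + (detail_type,)
        self._type_class[key] = cls
        self._type_canonical[key] = detail_type

    def register_relation(self, label: str, category: str) -> None:
        if category not in CATEGORIES:
            raise SchemaError(f"unknown relation category: {category!r}")
        canon = canonical_relation(label)
        if canon in self._relations:
            return
        self._relation_category_order.setdefault(category, ())
        self._relation_category_order[category] = self._relation_category_order[
            category
        ] + (label,)
        self._relations[canon] = RelationMeta(
            label=canon,
            category=category,
            polarity=_relation_polarity(canon),
            significant=_relation_significant(canon),
        )

    # -- (de)serialization ---------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "classes": {c: list(ts) for c, ts in self._classes.items()},
            "relations": {
                c: list(ls) for c, ls in self._relation_category_order.items()
            },
        }

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False, allow_unicode=True)

    def __eq__(self, other) -> bool:
        if not isinstance(other, OntologySchema):
            return NotImplemented
        return (
            self.name == other.name
            and self._classes == other._classes
            and self._relations == other._relations
        )

    def __repr__(self) -> str:
        return (
            f"OntologySchema(name={self.name!r}, classes={len(self._classes)}, "
            f"detail_types={len(self._type_canonical)}, "
            f"relations={len(self._relations)})"
        )


def load_schema(spec: str | Path | IO[str] | Mapping) -> OntologySchema:
    """Load and validate an ontology document (YAML path, stream, text or dict).

    Raises
    ------
    SchemaError
        On a malformed document, naming the offending entry.
    """
    if isinstance(spec, Mapping):
        doc = dict(spec)
    else:
        if isinstance(spec, Path):
            text = spec.read_text(encoding="utf-8")
        elif isinstance(spec, str):
            p = Path(spec)
            # a path-looking short string without newlines is treated as a file
            if spec and "\n" not in spec and p.is_file():
                text = p.read_text(encoding="utf-8")
            else:
                text = spec
        else:
            text = spec.read()
        try:
            doc = yaml.safe_load(text)
        except yaml.YAMLError as exc:
            raise SchemaError(f"unparseable schema document: {exc}") from exc
    if not isinstance(doc, Mapping):
        raise SchemaError("schema document must be a mapping")
    classes = doc.get("classes")
    relations = doc.get("relations", {})
    if not isinstance(classes, Mapping):
        raise SchemaError("schema document missing a 'classes' mapping")
    if not isinstance(relations, Mapping):
        raise SchemaError("'relations' must map category -> list of labels")
    for cls, dts in classes.items():
        if not isinstance(dts, (list, tuple)):
            raise SchemaError(f"class {cls!r}: detail types must be a list")
    return OntologySchema(classes, relations, name=str(doc.get("name", "")))


def default_schema(with_mention_extensions: bool = False) -> OntologySchema:
    """The packaged pig-gut-microbiota ontology (11 classes, 6 relation rows).

    With ``with_mention_extensions=True`` the two provenance-style relations
    used by the literature-mention ingester (``hasSource``, ``hasID``) and
    their object types (``PMID``, ``ConceptID``) are registered on top.
    """
    with resources.files("pgmkit.data").joinpath("ontology.yaml").open(
        "r", encoding="utf-8"
    ) as fh:
        schema = load_schema(fh)
    if with_mention_extensions:
        schema.register_relation("hasSource", "hasProperty")
        schema.register_relation("hasID", "hasProperty")
        schema.register_detail_type("Provenance", "PMID")
        schema.register_detail_type("Provenance", "ConceptID")
    return schema


def validate_entity(
    label: str, entity_type: str, schema: OntologySchema
) -> ValidationResult:
    """Accept iff ``entity_type`` (after alias normalization) is a known detail type."""
    if not label or not label.strip():
        return ValidationResult(False, "empty entity label")
    if not schema.has_detail_type(entity_type):
        return ValidationResult(False, f"unknown entity type: {entity_type!r}")
    return ValidationResult(True, canonical_type=schema.canonical_detail_type(entity_type))


def relation_category(label: str, schema: OntologySchema) -> RelationMeta:
    """Look up a relation label; unknown labels raise :class:`UnknownRelationError`."""
    return schema.relation(label)
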