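"""Metabolite origin classification (host / microbiota / both / food).

Given a reference table of per-metabolite origin flags, a queried metabolite
set is partitioned into host-only, microbiota-only, common-to-both and
unclassified (absent from the table, or present with neither flag); nothing
is silently dropped.  The food flag is orthogonal to that partition — a
feed-related metabolite may sit in any cell — and is summarized as a
percentage of the queried set.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import IO, Iterable, Mapping

from .graph import name_key

__all__ = ["OriginFlags", "OriginTable", "classify_origins", "food_fraction"]

_TRUE = {"1", "true", "yes", "y"}


@dataclass(frozen=True)
class OriginFlags:
    host: bool = False
    microbiota: bool = False
    food: bool = False


class OriginTable:
    """Metabolite name -> origin flags, keyed by normalized name."""

    def __init__(self, flags: Mapping[str, OriginFlags] | None = None):
        self._flags: dict[str, OriginFlags] = {}
        self._display: dict[str, str] = {}
        if flags:
            for name, f in flags.items():
                self.add(name, f)

    def add(self, name: str, flags: OriginFlags) -> None:
        self._flags[name_key(name)] = flags
        self._display[name_key(name)] = name

    def get(self, name: str) -> OriginFlags | None:
        return self._flags.get(name_key(name))

    def __len__(self) -> int:
        return len(self._flags)

    def __contains__(self, name: str) -> bool:
        return name_key(name) in self._flags

    def metabolites(self) -> list[str]:
        return sorted(self._display.values())

    @classmethod
    def from_tsv(cls, source: str | Path | IO[str]) -> "OriginTable":
        """Read a TSV with columns: metabolite, host, microbiota, food."""
        if isinstance(source, (str, Path)):
            fh = open(source, "r", encoding="utf-8")
            close = True
        else:
            fh, close = source, False
        try:
            reader = csv.DictReader(fh, delimiter="\t")
            required = {"metabolite", "host", "microbiota", "food"}
            if reader.fieldnames is None or not required.issubset(reader.fieldnames):
                raise ValueError(
                    f"origin table needs columns {sorted(required)}, "
                    f"got {reader.fieldnames}"
                )
            table = cls()
            for row in reader:
                table.add(
                    row["metabolite"],
                    OriginFlags(
                        host=row["host"].strip().lower() in _TRUE,
                        microbiota=row["microbiota"].strip().lower() in _TRUE,
                        food=row["food"].strip().lower() in _TRUE,
                    ),
                )
            return table
        finally:
            if close:
                fh.close()


def classify_origins(metabolites: Iterable[str], table: OriginTable) -> dict[str, int]:
    """Partition counts {host_only, microbiota_only, both, unclassified}.

    The four counts always sum to the number of distinct queried metabolites.
    """
    counts = {"host_only": 0, "microbiota_only": 0, "both": 0, "unclassified": 0}
    seen: set[str] = set()
    for m in metabolites:
        key = name_key(m)
        if key in seen:
            continue
        seen.add(key)
        flags = table.get(m)
        if flags is None or (not flags.host and not flags.microbiota):
            counts["unclassified"] += 1
        elif flags.host and flags.microbiota:
            counts["both"] += 1
        elif flags.host:
            counts["host_only"] += 1
        else:
            counts["microbiota_only"] += 1
    return counts


def food_fraction(metabolites: Iterable[str], table: OriginTable) -> float:
    """Percentage of queried metabolites carrying the food/feed flag,
    rounded half-even to 2 decimals (0.0 for an empty query set)."""
    seen: set[str] = set()
    flagged = 0
    for m in metabolites:
        key = name_key(m)
        if key in seen:
            continue
        seen.add(key)
        flags = table.get(m)
        if flags is not None and flags.food:
            flagged += 1
    if not seen:
        return 0.0
    return round(100.0 * flagged / len(seen), 2)
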