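"""Cell-type label harmonization.

Raw cell-type labels from different studies are inconsistent in casing and
granularity. This module normalizes label strings and attaches a three-level
typology (L3 most specific → L1 most general, 8 categories) plus a Cell
Ontology annotation, driven by a crosswalk table curated by experts.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import pandas as pd

from .errors import ConsistencyError, MappingError, ValidationError

logger = logging.getLogger(__name__)

#: The closed 8-category vocabulary of the most general (L1) typology level.
L1_CATEGORIES = frozenset(
    {
        "endothelial",
        "epithelial",
        "hematopoietic precursor",
        "immune",
        "mesenchymal",
        "neural",
        "mixed immune/epithelial",
        "unknown",
    }
)

#: Allowed Cell Ontology match levels.
MATCH_LEVELS = frozenset({"exactMatch", "narrowMatch"})

#: Label used for cells whose type is blank or unmapped.
UNKNOWN_LABEL = "unknown"

_WHITESPACE = re.compile(r"\s+")


def normalize_label(raw: str) -> str:
    """Normalize a cell-type label to the harmonized format.

    Lower-cases, strips surrounding whitespace and collapses internal runs
    of whitespace to single spaces. Idempotent. An empty (or all-whitespace)
    string maps to ``"unknown"``.
    """
    if raw is None:
        return UNKNOWN_LABEL
    label = _WHITESPACE.sub(" ", str(raw).strip()).lower()
    return label if label else UNKNOWN_LABEL


@dataclass(frozen=True)
class CrosswalkEntry:
    """Harmonized typology + ontology annotation for one original label."""

    l3: str
    l2: str
    l1: str
    cl_label: str = ""
    cl_id: str = ""
    match_level: str = "exactMatch"


@dataclass
class Crosswalk:
    """Mapping from normalized original labels to harmonized typology.

    ``entries`` is keyed by the *normalized* original label so crosswalk
    files may be written in any casing.
    """

    entries: dict[str, CrosswalkEntry] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for original, entry in self.entries.items():
            if entry.l1 not in L1_CATEGORIES:
                raise ValidationError(
                    f"L1 label {entry.l1!r} for {original!r} is not one of the "
                    f"8 L1 categories: {sorted(L1_CATEGORIES)}"
                )
            if entry.match_level not in MATCH_LEVELS:
                raise ValidationError(
                    f"match level {entry.match_level!r} for {original!r} not in "
                    f"{sorted(MATCH_LEVELS)}"
                )

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, label: str) -> bool:
        return normalize_label(label) in self.entries

    def lookup(self, label: str) -> CrosswalkEntry | None:
        return self.entries.get(normalize_label(label))

    @classmethod
    def from_records(cls, records) -> "Crosswalk":
        """Build from an iterable of dicts with keys original/l3/l2/l1/...

        Duplicate original labels are allowed only when their mappings agree;
        conflicting duplicates raise :class:`ConsistencyError`.
        """
        entries: dict[str, CrosswalkEntry] = {}
        for rec in records:
            original = normalize_label(rec["original"])
            entry = CrosswalkEntry(
                l3=normalize_label(rec["l3"]),
                l2=normalize_label(rec["l2"]),
                l1=normalize_label(rec["l1"]),
                cl_label=str(rec.get("cl_label", "") or ""),
                cl_id=str(rec.get("cl_id", "") or ""),
                match_level=str(rec.get("match_level", "exactMatch")),
            )
            if original in entries and entries[original] != entry:
                raise ConsistencyError(
                    f"duplicate original label {original!r} with conflicting mappings"
                )
            entries[original] = entry
        return cls(entries=entries)


def apply_crosswalk(
    cells: pd.DataFrame,
    crosswalk: Crosswalk,
    on_missing: str = "unknown",
) -> pd.DataFrame:
    """Attach L3/L2/L1 labels and ontology annotation to a cell table.

    Parameters
    ----------
    cells
        Cell table with a ``label_original`` column.
    crosswalk
        Curated label crosswalk.
    on_missing
        Policy for labels without a crosswalk entry: ``"error"`` raises a
        :class:`MappingError` listing them, ``"unknown"`` (default) maps all
        three levels to ``"unknown"``, ``"passthrough"`` uses the normalized
        original label at every level.

    Returns a copy; the input is not modified. Idempotent: re-applying with
    the same crosswalk changes nothing.
    """
    if on_missing not in {"error", "unknown", "passthrough"}:
        raise ValidationError(f"unknown on_missing policy {on_missing!r}")
    out = cells.copy()
    if out.empty:
        for col in ("label_l3", "label_l2", "label_l1", "cl_label", "cl_id", "match_level"):
            if col not in out.columns:
                out[col] = pd.Series(dtype=object)
        return out

    normalized = out["label_original"].map(normalize_label)
    missing = sorted(set(normalized) - set(crosswalk.entries))
    if missing:
        if on_missing == "error":
            raise MappingError(f"labels without crosswalk entries: {missing}")
        logger.warning(
            "%d label(s) without crosswalk entries handled by policy %r: %s",
            len(missing), on_missing, missing,
        )

    def _resolve(label: str) -> CrosswalkEntry:
        entry = crosswalk.entries.get(label)
        if entry is not None:
            return entry
        if on_missing == "passthrough":
            return CrosswalkEntry(l3=label, l2=label, l1=UNKNOWN_LABEL)
        return CrosswalkEntry(l3=UNKNOWN_LABEL, l2=UNKNOWN_LABEL, l1=UNKNOWN_LABEL)

    resolved = normalized.map(_resolve)
    out["label_l3"] = resolved.map(lambda e: e.l3)
    out["label_l2"] = resolved.map(lambda e: e.l2)
    out["label_l1"] = resolved.map(lambda e: e.l1)
    out["cl_label"] = resolved.map(lambda e: e.cl_label)
    out["cl_id"] = resolved.map(lambda e: e.cl_id)
    out["match_level"] = resolved.map(lambda e: e.match_level)
    return out


def typology_summary(crosswalk: Crosswalk) -> dict[str, int]:
    """Count distinct labels at each typology level of a crosswalk."""
    entries = crosswalk.entries.values()
    return {
        "original": len(crosswalk.entries),
        "l3": len({e.l3 for e in entries}),
        "l2": len({e.l2 for e in entries}),
        "l1": len({e.l1 for e in entries}),
    }
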