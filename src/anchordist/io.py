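"""Reading and writing the pipeline's CSV artifacts.

All tables are plain comma-separated UTF-8 with one header row and ``.`` as
the decimal separator. Cell tables are pandas DataFrames with the canonical
columns ``cell_id, x, y[, z], label_original`` plus optional harmonized
label and metadata columns; coordinates are stored in micrometers (raw
pixel units are converted on read and never kept).
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import (
    DimensionalityError,
    ParseError,
    SchemaError,
    ValidationError,
)
from .harmonize import Crosswalk, UNKNOWN_LABEL, normalize_label

logger = logging.getLogger(__name__)

#: Metadata columns recognized (case-insensitively) in nodes files.
METADATA_COLUMNS = ("dataset_id", "donor_id", "region", "subregion", "condition")

#: Canonical cell-table columns in output order.
CELL_COLUMNS = (
    "cell_id", "x", "y", "z",
    "label_original", "label_l3", "label_l2", "label_l1",
    "cl_label", "cl_id", "match_level",
) + METADATA_COLUMNS

_LABEL_SYNONYMS = ("name", "cell_type", "label", "label_original", "celltype")
_ID_SYNONYMS = ("cell_id", "id")

#: Fixed 12-color palette cycled for color maps (hex, deterministic).
DEFAULT_PALETTE = (
    "#1f77b4", "#ff7f0e", "#2ca02c", "#d62728", "#9467bd", "#8c564b",
    "#e377c2", "#7f7f7f", "#bcbd22", "#17becf", "#aec7e8", "#ffbb78",
)


def _header_map(columns) -> dict[str, str]:
    """Map lower-cased, stripped header names to the actual header strings."""
    return {str(c).strip().lower(): c for c in columns}


def is_3d(cells: pd.DataFrame) -> bool:
    """Whether a cell table carries a complete z column."""
    return "z" in cells.columns and cells["z"].notna().all() and len(cells) > 0


def _coerce_coordinate(raw: pd.Series, column: str) -> pd.Series:
    values = pd.to_numeric(raw, errors="coerce")
    bad = values.isna() & raw.notna() & (raw.astype(str).str.strip() != "")
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise ParseError(
            f"non-numeric {column!r} coordinate at data row {row}: "
            f"{raw.iloc[row]!r}"
        )
    return values.astype(float)


def read_nodes(
    path,
    pixel_size: float = 1.0,
    id_policy: str = "row_index",
) -> pd.DataFrame:
    """Read a nodes.csv cell table.

    The file must have a header row with columns for x, y and the cell-type
    name (``name`` or ``cell_type``, matched case-insensitively); ``z`` is
    optional and, when present, must be filled for every cell or for none.
    Coordinates are multiplied by ``pixel_size`` so downstream stages always
    work in μm. Row order is preserved, and when the file has no id column,
    ``cell_id`` is assigned by ``id_policy`` (default: 0-based row index).
    Blank or missing labels become ``"unknown"``; unrecognized extra columns
    are carried through as metadata.
    """
    if pixel_size <= 0:
        raise ValidationError("pixel_size must be > 0")
    raw = pd.read_csv(path, dtype=object, skipinitialspace=True)
    headers = _header_map(raw.columns)

    for required in ("x", "y"):
        if required not in headers:
            raise SchemaError(f"nodes file {path} is missing required column {required!r}")
    label_col = next((headers[s] for s in _LABEL_SYNONYMS if s in headers), None)
    if label_col is None:
        raise SchemaError(
            f"nodes file {path} is missing a cell label column "
            f"(expected one of {_LABEL_SYNONYMS})"
        )

    out = pd.DataFrame(index=raw.index)

    id_col = next((headers[s] for s in _ID_SYNONYMS if s in headers), None)
    if id_col is not None:
        ids = raw[id_col]
        if ids.duplicated().any():
            raise ValidationError(f"duplicate cell_id values in {path}")
        try:
            out["cell_id"] = pd.to_numeric(ids)
        except (ValueError, TypeError):
            out["cell_id"] = ids
    elif id_policy == "row_index":
        out["cell_id"] = np.arange(len(raw), dtype=int)
    else:
        raise ValidationError(f"unknown id_policy {id_policy!r}")

    out["x"] = _coerce_coordinate(raw[headers["x"]], "x") * pixel_size
    out["y"] = _coerce_coordinate(raw[headers["y"]], "y") * pixel_size

    if "z" in headers:
        z = _coerce_coordinate(raw[headers["z"]], "z")
        if z.notna().any():
            if z.isna().any():
                raise DimensionalityError(
                    f"{path}: some cells have a z coordinate and some do not"
                )
            out["z"] = z * pixel_size
        # an entirely blank z column is treated as 2D

    out["label_original"] = raw[label_col].map(
        lambda v: UNKNOWN_LABEL if pd.isna(v) else normalize_label(v)
    )

    consumed = {headers["x"], headers["y"], label_col}
    if "z" in headers:
        consumed.add(headers["z"])
    if id_col is not None:
        consumed.add(id_col)
    for col in raw.columns:
        if col in consumed:
            continue
        key = str(col).strip().lower()
        out[key if key in METADATA_COLUMNS else col] = raw[col]
    return out


def write_cells(cells: pd.DataFrame, path) -> None:
    """Write a cell table, canonical columns first, extras after."""
    ordered = [c for c in CELL_COLUMNS if c in cells.columns]
    extras = [c for c in cells.columns if c not in ordered]
    cells[ordered + extras].to_csv(path, index=False)


def read_cells(path) -> pd.DataFrame:
    """Read a cell table previously written by :func:`write_cells`."""
    cells = pd.read_csv(path)
    if "cell_id" not in cells.columns:
        raise SchemaError(f"cell table {path} is missing the cell_id column")
    for required in ("x", "y"):
        if required not in cells.columns:
            raise SchemaError(f"cell table {path} is missing column {required!r}")
    return cells


def write_edges(edges: pd.DataFrame, path) -> None:
    """Write an edge table as ``source_id,anchor_id,distance``.

    Distances use Python float repr (17 significant digits when needed), so
    a round-trip read reproduces the table exactly.
    """
    for col in ("source_id", "anchor_id", "distance"):
        if col not in edges.columns:
            raise SchemaError(f"edge table is missing column {col!r}")
    if edges["source_id"].duplicated().any():
        raise ValidationError("edge table has more than one row per source_id")
    if len(edges) and (edges["distance"] < 0).any():
        raise ValidationError("edge distances must be non-negative")
    edges[["source_id", "anchor_id", "distance"]].to_csv(path, index=False)


def read_edges(path) -> pd.DataFrame:
    """Read an edges.csv file."""
    edges = pd.read_csv(path)
    headers = _header_map(edges.columns)
    missing = [c for c in ("source_id", "anchor_id", "distance") if c not in headers]
    if missing:
        raise SchemaError(f"edges file {path} is missing columns {missing}")
    edges = edges.rename(columns={headers[k]: k for k in ("source_id", "anchor_id", "distance")})
    edges["distance"] = edges["distance"].astype(float)
    return edges


def make_colormap(labels, colors: dict | None = None) -> pd.DataFrame:
    """Assign a hex color to each label, cycling a fixed palette.

    Deterministic given label order; explicit ``colors`` entries override
    the palette. Duplicate labels are rejected.
    """
    labels = list(labels)
    if not labels:
        raise ValidationError("label list must be non-empty")
    if len(set(labels)) != len(labels):
        raise ValidationError("duplicate labels in color map input")
    colors = colors or {}
    assigned = [
        colors.get(label, DEFAULT_PALETTE[i % len(DEFAULT_PALETTE)])
        for i, label in enumerate(labels)
    ]
    return pd.DataFrame({"label": labels, "hex_color": assigned})


def write_colormap(labels, path, colors: dict | None = None) -> pd.DataFrame:
    """Write a ``label,hex_color`` color map CSV; returns the table."""
    table = make_colormap(labels, colors)
    table.to_csv(path, index=False)
    return table


def load_synthetic_crosswalk() -> Crosswalk:
    """The bundled crosswalk for the synthetic generators' label
    vocabulary (synthetic fixture, not the published mapping), so
    harmonization can be exercised end to end without external files."""
    from importlib.resources import as_file, files

    with as_file(files("anchordist").joinpath("data/synthetic_crosswalk.csv")) as path:
        return read_crosswalk(path)


_CROSSWALK_SYNONYMS = {
    "original": ("original", "original_label", "original_cell_type", "name"),
    "l3": ("l3", "level3", "level_three", "level 3"),
    "l2": ("l2", "level2", "level_two", "level 2"),
    "l1": ("l1", "level1", "level_one", "level 1"),
    "cl_label": ("cl_label", "cl label", "cllabel", "cell_ontology_label"),
    "cl_id": ("cl_id", "cl id", "clid", "cell_ontology_id"),
    "match_level": ("match_level", "match level", "matchlevel", "match"),
}


def read_crosswalk(path) -> Crosswalk:
    """Read a cell-type crosswalk CSV into a :class:`Crosswalk`.

    Expects columns for the original label, L3, L2, L1, Cell Ontology label
    and ID, and the match level (header names matched case-insensitively
    with common synonyms). Duplicate original labels must map consistently;
    match levels outside {exactMatch, narrowMatch} are rejected.
    """
    raw = pd.read_csv(path, dtype=object)
    headers = _header_map(raw.columns)
    resolved: dict[str, str] = {}
    for canonical, synonyms in _CROSSWALK_SYNONYMS.items():
        col = next((headers[s] for s in synonyms if s in headers), None)
        if col is None and canonical in ("original", "l3", "l2", "l1"):
            raise SchemaError(f"crosswalk {path} is missing the {canonical!r} column")
        if col is not None:
            resolved[canonical] = col

    records = []
    for _, row in raw.iterrows():
        rec = {key: row[col] for key, col in resolved.items()}
        rec.setdefault("cl_label", "")
        rec.setdefault("cl_id", "")
        rec.setdefault("match_level", "exactMatch")
        if rec.get("match_level") is None or pd.isna(rec["match_level"]):
            rec["match_level"] = "exactMatch"
        records.append(rec)
    return Crosswalk.from_records(records)
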