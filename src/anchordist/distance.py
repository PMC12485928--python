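"""Cell-to-nearest-anchor-cell distance graphs.

An *anchor cell* is a cell type of interest (by default an endothelial
cell); for every non-anchor cell the Euclidean distance to its nearest
anchor defines one linkage (edge), retained only when it lies within a
maximum distance threshold (200 μm by default). Works identically in 2D
and 3D; serial-section stacks without a true z coordinate are treated as
independent 2D tables.

Exact nearest neighbors are found with a k-d tree; a brute-force all-pairs
scan with the same contract is provided as an independent oracle for
verification. Ties (several anchors exactly equidistant) are broken
deterministically by the lowest anchor ``cell_id``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .errors import DimensionalityError, SchemaError
from .harmonize import normalize_label

logger = logging.getLogger(__name__)

EDGE_COLUMNS = ("source_id", "anchor_id", "distance")

_LEVEL_COLUMNS = {
    "original": "label_original",
    "l1": "label_l1",
    "l2": "label_l2",
    "l3": "label_l3",
}


def level_column(level: str) -> str:
    """Cell-table column holding labels at a typology level."""
    try:
        return _LEVEL_COLUMNS[level]
    except KeyError:
        raise SchemaError(f"unknown typology level {level!r}") from None


@dataclass
class AnchorSelection:
    """Boolean selection of anchor cells within a cell table."""

    anchor_label: str
    level: str
    mask: np.ndarray  # boolean, aligned with the cell table's rows

    @property
    def n_anchors(self) -> int:
        return int(self.mask.sum())


def select_anchors(cells: pd.DataFrame, anchor_label: str, level: str = "l1") -> AnchorSelection:
    """Mark the cells whose label at ``level`` equals ``anchor_label``.

    Labels are compared after normalization, so any casing works. Selecting
    at a harmonized level requires the table to be harmonized first. An
    empty selection is not an error; it is reported and handled downstream.
    """
    column = level_column(level)
    if column not in cells.columns or cells[column].isna().all() and len(cells) > 0:
        raise SchemaError(
            f"cells carry no labels at level {level!r} "
            f"(column {column!r} missing or empty) — harmonize first"
        )
    target = normalize_label(anchor_label)
    labels = cells[column].map(normalize_label)
    mask = (labels == target).to_numpy()
    logger.info("selected %d anchor cells with %s=%r", int(mask.sum()), level, target)
    return AnchorSelection(anchor_label=target, level=level, mask=mask)


def coordinates(cells: pd.DataFrame) -> np.ndarray:
    """(n, 2) or (n, 3) float coordinate matrix; validates dimensionality."""
    if "z" in cells.columns and len(cells) > 0:
        z = cells["z"]
        if z.notna().any():
            if z.isna().any():
                raise DimensionalityError("mixed 2D/3D table: z present for only some cells")
            return cells[["x", "y", "z"]].to_numpy(dtype=float)
    return cells[["x", "y"]].to_numpy(dtype=float)


def _euclidean(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Euclidean distances between matching rows (the one distance formula
    used by both the k-d tree path and the brute-force oracle, so their
    outputs are comparable to the last bit)."""
    return np.sqrt(((a - b) ** 2).sum(axis=-1))


def _assemble_edges(source_ids, anchor_ids, distances, max_distance) -> pd.DataFrame:
    edges = pd.DataFrame(
        {"source_id": source_ids, "anchor_id": anchor_ids, "distance": distances}
    )
    if max_distance is not None and np.isfinite(max_distance):
        edges = edges[edges["distance"] <= max_distance]  # inclusive threshold
    return edges.reset_index(drop=True)


def _empty_edges() -> pd.DataFrame:
    return pd.DataFrame({"source_id": [], "anchor_id": [], "distance": []})


def nearest_anchor_edges(
    cells: pd.DataFrame,
    anchors: AnchorSelection,
    max_distance: float | None = 200.0,
) -> pd.DataFrame:
    """Link every non-anchor cell to its nearest anchor within ``max_distance``.

    Returns an edge table with one row per non-anchor cell whose nearest
    anchor lies at Euclidean distance ≤ ``max_distance`` (inclusive);
    anchor cells themselves receive no edges. ``max_distance=None`` (or
    inf) keeps every linkage. With zero anchors an empty table is returned
    and a warning logged.
    """
    mask = np.asarray(anchors.mask, dtype=bool)
    if mask.shape[0] != len(cells):
        raise SchemaError("anchor mask length does not match cell table")
    if not mask.any():
        logger.warning("no anchor cells selected; returning empty edge table")
        return _empty_edges()
    coords = coordinates(cells)
    ids = cells["cell_id"].to_numpy()
    anchor_coords = coords[mask]
    anchor_ids = ids[mask]
    source_coords = coords[~mask]
    source_ids = ids[~mask]
    if len(source_ids) == 0:
        return _empty_edges()

    tree = cKDTree(anchor_coords)
    nn_dist, nn_idx = tree.query(source_coords, k=1)

    # Resolve potential ties exactly: re-examine all anchors within a hair of
    # the reported nearest distance and pick the lowest anchor cell_id among
    # those at the exact minimum (recomputed with the shared formula).
    radius = nn_dist * (1 + 1e-9) + 1e-12
    candidates = tree.query_ball_point(source_coords, radius)
    best_idx = np.empty(len(source_ids), dtype=int)
    best_dist = np.empty(len(source_ids), dtype=float)
    for i, cand in enumerate(candidates):
        cand = np.asarray(cand if len(cand) else [nn_idx[i]], dtype=int)
        d = _euclidean(anchor_coords[cand], source_coords[i])
        dmin = d.min()
        tied = cand[d == dmin]
        best_idx[i] = tied[np.argmin(anchor_ids[tied])]
        best_dist[i] = dmin
    return _assemble_edges(source_ids, anchor_ids[best_idx], best_dist, max_distance)


def brute_force_nearest(
    cells: pd.DataFrame,
    anchors: AnchorSelection,
    max_distance: float | None = 200.0,
) -> pd.DataFrame:
    """Exhaustive all-pairs reference with the same contract as
    :func:`nearest_anchor_edges`. Intended for verification at small n."""
    mask = np.asarray(anchors.mask, dtype=bool)
    if mask.shape[0] != len(cells):
        raise SchemaError("anchor mask length does not match cell table")
    if not mask.any():
        logger.warning("no anchor cells selected; returning empty edge table")
        return _empty_edges()
    coords = coordinates(cells)
    ids = cells["cell_id"].to_numpy()
    anchor_coords = coords[mask]
    anchor_ids = ids[mask]
    source_coords = coords[~mask]
    source_ids = ids[~mask]
    if len(source_ids) == 0:
        return _empty_edges()

    best_idx = np.empty(len(source_ids), dtype=int)
    best_dist = np.empty(len(source_ids), dtype=float)
    for i, p in enumerate(source_coords):
        d = _euclidean(anchor_coords, p)
        dmin = d.min()
        tied = np.flatnonzero(d == dmin)
        best_idx[i] = tied[np.argmin(anchor_ids[tied])]
        best_dist[i] = dmin
    return _assemble_edges(source_ids, anchor_ids[best_idx], best_dist, max_distance)
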