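"""Anchor-cell-centric neighborhood analysis.

For every anchor cell (endothelial cells in the motivating use case) the k
nearest neighboring cells — any type, anchors included, the center itself
excluded — define a composition vector of cell-type fractions. K-means over
these vectors yields recurring microenvironment classes; clusters that are
compositionally similar and spatially co-localized may then be merged into
named neighborhoods (a judgment step, so merging is user-driven with an
advisory suggestion helper). Radial analysis recomputes compositions over
concentric KNN windows of increasing size, and enrichment quantifies the
anchor-type fraction of each neighborhood, normalized per donor by the
anchor-type fraction of the enclosing tissue subregion.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from sklearn.cluster import KMeans

from .distance import AnchorSelection, coordinates, level_column
from .errors import MappingError, SchemaError, SizeError, ValidationError

logger = logging.getLogger(__name__)


def _knn_indices(coords: np.ndarray, query_rows: np.ndarray, k: int) -> np.ndarray:
    """(n_query, k) row indices of the k nearest cells to each query cell,
    excluding the query cell itself."""
    if k >= len(coords):
        raise SizeError(f"k={k} neighbors requested but only {len(coords)} cells exist")
    tree = cKDTree(coords)
    _, idx = tree.query(coords[query_rows], k=k + 1)
    idx = np.atleast_2d(idx)
    out = np.empty((len(query_rows), k), dtype=int)
    for i, row in enumerate(idx):
        row = row[row != query_rows[i]]  # drop self; ties keep k others
        out[i] = row[:k]
    return out


def knn_neighbor_composition(
    cells: pd.DataFrame,
    anchors: AnchorSelection,
    k: int = 50,
    level: str = "l3",
) -> pd.DataFrame:
    """Per-anchor neighbor-type fraction vectors at window size ``k``.

    Returns a DataFrame indexed by anchor ``cell_id`` whose columns are the
    full label vocabulary of the table at ``level`` (sorted); each row sums
    to 1. The center anchor is excluded from its own window; anchor-type
    cells do count as neighbors.
    """
    label_col = level_column(level)
    if label_col not in cells.columns:
        raise SchemaError(f"cells are not harmonized at level {level!r}")
    mask = np.asarray(anchors.mask, dtype=bool)
    vocabulary = sorted(cells[label_col].astype(str).unique())
    if not mask.any():
        logger.warning("no anchors selected; composition matrix is empty")
        out = pd.DataFrame(columns=vocabulary, dtype=float)
        out.index.name = "cell_id"
        return out

    coords = coordinates(cells)
    query_rows = np.flatnonzero(mask)
    neighbor_idx = _knn_indices(coords, query_rows, k)

    codes = pd.Categorical(cells[label_col].astype(str), categories=vocabulary).codes
    counts = np.zeros((len(query_rows), len(vocabulary)), dtype=float)
    rows = np.repeat(np.arange(len(query_rows)), k)
    np.add.at(counts, (rows, codes[neighbor_idx.ravel()]), 1.0)

    out = pd.DataFrame(
        counts / k,
        index=pd.Index(cells["cell_id"].to_numpy()[query_rows], name="cell_id"),
        columns=vocabulary,
    )
    out.attrs["k"] = k
    out.attrs["level"] = level
    return out


@dataclass
class NeighborhoodModel:
    """Clustered anchor microenvironments with an optional merge map.

    ``assignments`` maps anchor cell_id → initial k-means cluster id;
    ``merge_map`` (total over cluster ids) renames/merges clusters into the
    final neighborhoods exposed by ``final_labels``.
    """

    k_initial: int
    seed: int
    assignments: pd.Series  # index: anchor cell_id, values: int cluster id
    centroids: np.ndarray | None = None
    merge_map: dict[int, str] | None = field(default=None)

    @property
    def cluster_ids(self) -> list[int]:
        return sorted(pd.unique(self.assignments))

    @property
    def final_labels(self) -> pd.Series:
        """Anchor cell_id → neighborhood name (cluster id as string when no
        merge map has been applied)."""
        if self.merge_map is None:
            return self.assignments.map(lambda c: str(c))
        return self.assignments.map(self.merge_map)

    @property
    def neighborhood_names(self) -> list[str]:
        return sorted(pd.unique(self.final_labels))


def cluster_compositions(matrix: pd.DataFrame, n_clusters: int = 20, seed: int = 0) -> NeighborhoodModel:
    """K-means over raw composition vectors (k-means++ init, 10 restarts,
    tolerance 1e-4, seeded — reproducible for a fixed seed). No feature
    standardization: all fractions already share one scale."""
    if len(matrix) < n_clusters:
        raise SizeError(
            f"{len(matrix)} composition rows cannot support {n_clusters} clusters"
        )
    km = KMeans(
        n_clusters=n_clusters,
        init="k-means++",
        n_init=10,
        tol=1e-4,
        random_state=seed,
    ).fit(matrix.to_numpy())
    assignments = pd.Series(km.labels_.astype(int), index=matrix.index, name="cluster")
    return NeighborhoodModel(
        k_initial=n_clusters, seed=seed, assignments=assignments, centroids=km.cluster_centers_
    )


def merge_clusters(model: NeighborhoodModel, merge_map: dict) -> NeighborhoodModel:
    """Apply a total cluster-id → neighborhood-name map to a fitted model."""
    missing = [c for c in model.cluster_ids if c not in merge_map]
    if missing:
        raise MappingError(f"merge map is missing cluster ids {missing}")
    return replace(model, merge_map={int(c): str(n) for c, n in merge_map.items()})


def _cosine_similarity(a: np.ndarray, b: np.ndarray) -> float:
    denom = np.linalg.norm(a) * np.linalg.norm(b)
    return float(a @ b / denom) if denom > 0 else 0.0


def suggest_merges(
    model: NeighborhoodModel,
    matrix: pd.DataFrame,
    composition_similarity_threshold: float = 0.9,
    colocalization_threshold: float = 0.25,
    cells: pd.DataFrame | None = None,
    anchors: AnchorSelection | None = None,
    n_spatial_neighbors: int = 10,
    n_target: int | None = None,
) -> dict[int, str]:
    """Propose a merge map collapsing similar, co-localized clusters.

    Greedy agglomeration: repeatedly merge the pair of cluster groups with
    the highest centroid cosine similarity, provided the similarity meets
    ``composition_similarity_threshold`` and (when spatial data is given)
    their co-occurrence — the larger, over the two directions, of the
    fraction of one group's anchors having an anchor of the other among
    their ``n_spatial_neighbors`` nearest anchors — meets
    ``colocalization_threshold``. If ``n_target`` is given, thresholds are
    ignored and merging continues to exactly that many neighborhoods
    (mirroring a judgment-driven 20 → n merge). Advisory only: the returned
    map is a candidate for :func:`merge_clusters`; the user's map remains
    authoritative.
    """
    if not (0 < composition_similarity_threshold <= 1):
        raise ValidationError("composition_similarity_threshold must be in (0, 1]")
    if not (0 < colocalization_threshold <= 1):
        raise ValidationError("colocalization_threshold must be in (0, 1]")
    cluster_ids = model.cluster_ids
    values = matrix.to_numpy()
    labels = model.assignments.loc[matrix.index].to_numpy()

    # per-anchor neighbor clusters, for co-occurrence
    neighbor_clusters = None
    if cells is not None and anchors is not None:
        mask = np.asarray(anchors.mask, dtype=bool)
        anchor_coords = coordinates(cells)[mask]
        anchor_ids = cells["cell_id"].to_numpy()[mask]
        order = pd.Series(np.arange(len(anchor_ids)), index=anchor_ids)
        rows = order.loc[matrix.index].to_numpy()
        m = min(n_spatial_neighbors, len(anchor_coords) - 1)
        if m >= 1:
            tree = cKDTree(anchor_coords[rows])
            _, idx = tree.query(anchor_coords[rows], k=m + 1)
            neighbor_clusters = labels[np.atleast_2d(idx)[:, 1:]]

    groups = {cid: [cid] for cid in cluster_ids}

    def group_centroid(members):
        sel = np.isin(labels, members)
        return values[sel].mean(axis=0)

    def group_coloc(members_a, members_b):
        if neighbor_clusters is None:
            return 1.0
        in_a = np.isin(labels, members_a)
        in_b = np.isin(labels, members_b)
        has_b = np.isin(neighbor_clusters, members_b).any(axis=1)
        has_a = np.isin(neighbor_clusters, members_a).any(axis=1)
        frac_a = has_b[in_a].mean() if in_a.any() else 0.0
        frac_b = has_a[in_b].mean() if in_b.any() else 0.0
        return float(max(frac_a, frac_b))

    while len(groups) > 1:
        if n_target is not None and len(groups) <= n_target:
            break
        keys = sorted(groups)
        best = None
        for i, a in enumerate(keys):
            ca = group_centroid(groups[a])
            for b in keys[i + 1:]:
                sim = _cosine_similarity(ca, group_centroid(groups[b]))
                if n_target is None:
                    if sim < composition_similarity_threshold:
                        continue
                    if group_coloc(groups[a], groups[b]) < colocalization_threshold:
                        continue
                if best is None or sim > best[0]:
                    best = (sim, a, b)
        if best is None:
            break
        _, a, b = best
        groups[a] = groups[a] + groups[b]
        del groups[b]

    merge_map: dict[int, str] = {}
    for i, key in enumerate(sorted(groups)):
        name = f"N{i}"
        for member in groups[key]:
            merge_map[member] = name
    return merge_map


def radial_composition(
    cells: pd.DataFrame,
    anchors: AnchorSelection,
    model: NeighborhoodModel,
    window_sizes=(5, 10, 30, 50, 100, 300),
    level: str = "l3",
) -> pd.DataFrame:
    """Mean composition per (neighborhood, window size) over concentric KNN
    windows, probing how neighborhood composition varies with spatial
    scale. At a window equal to the clustering k this reproduces the
    per-neighborhood means of the clustering matrix exactly."""
    final = model.final_labels
    frames = []
    for w in window_sizes:
        comp = knn_neighbor_composition(cells, anchors, k=int(w), level=level)
        comp = comp.loc[final.index]
        grouped = comp.groupby(final).mean()
        grouped.insert(0, "window", int(w))
        frames.append(grouped)
    out = pd.concat(frames)
    out.index.name = "neighborhood"
    return out.reset_index().set_index(["neighborhood", "window"]).sort_index()


def anchor_fraction_per_anchor(
    cells: pd.DataFrame,
    anchors: AnchorSelection,
    k: int = 50,
) -> pd.Series:
    """Fraction of anchor-type cells among each anchor's k nearest
    neighbors (the per-window anchor enrichment)."""
    mask = np.asarray(anchors.mask, dtype=bool)
    coords = coordinates(cells)
    query_rows = np.flatnonzero(mask)
    if len(query_rows) == 0:
        return pd.Series(dtype=float, name="anchor_fraction")
    neighbor_idx = _knn_indices(coords, query_rows, k)
    frac = mask[neighbor_idx].mean(axis=1)
    return pd.Series(
        frac, index=pd.Index(cells["cell_id"].to_numpy()[query_rows], name="cell_id"),
        name="anchor_fraction",
    )


def ec_enrichment(
    cells: pd.DataFrame,
    anchors: AnchorSelection,
    model: NeighborhoodModel,
    k: int = 50,
) -> pd.Series:
    """Anchor-type (EC) enrichment per neighborhood: the mean, over member
    anchors, of the fraction of anchor-type cells in their windows."""
    per_anchor = anchor_fraction_per_anchor(cells, anchors, k=k)
    final = model.final_labels
    return per_anchor.loc[final.index].groupby(final).mean().rename("ec_enrichment")


def normalized_ec_enrichment(
    cells: pd.DataFrame,
    anchors: AnchorSelection,
    model: NeighborhoodModel,
    k: int = 50,
    subregion_key: str = "subregion",
    donor_key: str = "donor_id",
) -> pd.DataFrame:
    """Per-donor subregion-normalized anchor enrichment.

    For every donor × neighborhood × subregion: fold change = (mean window
    anchor fraction of that group's anchors) ÷ (fraction of all the
    donor-subregion's cells that are anchor-type). Records whose
    denominator is zero are flagged and carry no fold-change number.
    """
    for key in (subregion_key, donor_key):
        if key not in cells.columns:
            raise SchemaError(f"cells are missing the {key!r} column")
    mask = np.asarray(anchors.mask, dtype=bool)
    per_anchor = anchor_fraction_per_anchor(cells, anchors, k=k)

    meta = cells.set_index("cell_id")
    table = pd.DataFrame(
        {
            "anchor_fraction": per_anchor,
            "neighborhood": model.final_labels,
            "donor_id": meta.loc[per_anchor.index, donor_key].to_numpy(),
            "subregion": meta.loc[per_anchor.index, subregion_key].to_numpy(),
        }
    )
    background = (
        pd.DataFrame(
            {
                "is_anchor": mask,
                "donor_id": cells[donor_key].to_numpy(),
                "subregion": cells[subregion_key].to_numpy(),
            }
        )
        .groupby(["donor_id", "subregion"])["is_anchor"]
        .mean()
    )

    rows = []
    grouped = table.groupby(["donor_id", "subregion", "neighborhood"])["anchor_fraction"].mean()
    for (donor, subregion, name), numerator in grouped.items():
        denominator = float(background.loc[(donor, subregion)])
        zero = denominator == 0
        rows.append(
            {
                "neighborhood": name,
                "donor_id": donor,
                "subregion": subregion,
                "ec_fraction_neighborhood": float(numerator),
                "ec_fraction_subregion": denominator,
                "fold_change": float("nan") if zero else float(numerator) / denominator,
                "zero_background": zero,
            }
        )
    return pd.DataFrame(rows)


def neighborhood_percentages(
    model: NeighborhoodModel,
    cells: pd.DataFrame,
    group_key,
) -> pd.DataFrame:
    """Per-group neighborhood fractions (denominator: anchors in the
    group). Rows sum to 1; groups with zero anchors are omitted with a
    warning. ``group_key`` may be one column name or a list."""
    keys = [group_key] if isinstance(group_key, str) else list(group_key)
    for key in keys:
        if key not in cells.columns:
            raise SchemaError(f"unknown group key {key!r}")
    final = model.final_labels
    meta = cells.set_index("cell_id")
    table = pd.DataFrame({"neighborhood": final})
    for key in keys:
        table[key] = meta.loc[final.index, key].to_numpy()
    counts = (
        table.groupby(keys + ["neighborhood"]).size().unstack(fill_value=0)
    )
    n_groups_total = cells.groupby(keys).size()
    empty = set(map(tuple if len(keys) > 1 else lambda v: v, n_groups_total.index)) - set(
        counts.index
    )
    if empty:
        logger.warning("%d group(s) contain zero anchors and are omitted", len(empty))
    return counts.div(counts.sum(axis=1), axis=0)
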