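"""Distance-distribution summaries.

Summarizes cell-to-nearest-anchor distance distributions per cell type and
grouping (region, condition, donor, dataset): count, mean, standard
deviation, median, quartiles, interquartile range, and the coefficient of
variation CV = 100 × sd / mean (sample sd, n−1 denominator; reported in
percent). Quartiles use linear interpolation on the sorted values.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .distance import level_column
from .errors import ConsistencyError, InsufficientDataError, SchemaError, ValidationError

SUMMARY_COLUMNS = ("n", "mean", "sd", "median", "q1", "q3", "iqr", "cv")


def coefficient_of_variation(values) -> float:
    """CV in percent: 100 × sample standard deviation / mean.

    Requires at least two values and a strictly positive mean. A CV of 0
    means no variation; larger values mean greater relative variability
    regardless of absolute distances.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise InsufficientDataError("CV requires at least 2 values")
    mean = values.mean()
    if mean <= 0:
        raise ValidationError("CV requires a strictly positive mean")
    return float(100.0 * values.std(ddof=1) / mean)


def _summarize_group(distances: np.ndarray) -> dict:
    n = distances.size
    mean = float(distances.mean())
    sd = float(distances.std(ddof=1)) if n >= 2 else float("nan")
    q1, median, q3 = (float(q) for q in np.percentile(distances, [25, 50, 75]))
    cv = 100.0 * sd / mean if n >= 2 and mean > 0 else float("nan")
    return {
        "n": n,
        "mean": mean,
        "sd": sd,
        "median": median,
        "q1": q1,
        "q3": q3,
        "iqr": q3 - q1,
        "cv": cv,
    }


def summarize_distances(
    edges: pd.DataFrame,
    cells: pd.DataFrame,
    level: str = "l3",
    group_keys: list[str] | None = None,
) -> pd.DataFrame:
    """One summary row per (group, cell type) with at least one edge.

    ``group_keys`` name metadata columns of the cell table (e.g.
    ``["region"]``); groups and cell types with zero edges are omitted, and
    cells without an edge (beyond the distance threshold) do not enter the
    statistics. Output is independent of input row order.
    """
    group_keys = list(group_keys or [])
    label_col = level_column(level)
    if label_col not in cells.columns:
        raise SchemaError(f"cells are not harmonized at level {level!r} ({label_col} missing)")
    for key in group_keys:
        if key not in cells.columns:
            raise SchemaError(f"unknown group key {key!r}")

    lookup = cells.set_index("cell_id")
    missing = ~edges["source_id"].isin(lookup.index)
    if missing.any():
        raise ConsistencyError(
            f"{int(missing.sum())} edge source_id value(s) not present in the cell table"
        )

    annotated = edges[["source_id", "distance"]].copy()
    joined = lookup.loc[annotated["source_id"], [label_col] + group_keys]
    annotated["cell_type"] = joined[label_col].to_numpy()
    for key in group_keys:
        annotated[key] = joined[key].to_numpy()

    keys = group_keys + ["cell_type"]
    rows = []
    for group_values, part in annotated.groupby(keys, dropna=False, sort=True):
        if not isinstance(group_values, tuple):
            group_values = (group_values,)
        row = dict(zip(keys, group_values))
        row.update(_summarize_group(part["distance"].to_numpy(dtype=float)))
        rows.append(row)
    return pd.DataFrame(rows, columns=keys + list(SUMMARY_COLUMNS))
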