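"""Synthetic tissue with known ground truth.

Two generators make every pipeline stage testable without external data:

* :func:`generate_vessel_tissue` lays anchor (endothelial-like) cells along
  vessel polylines and places other cell types at type-specific radial
  distance laws from the vasculature, so nearest-anchor distance
  distributions have known quantiles;
* :func:`generate_planted_neighborhoods` tiles the field with zones whose
  cell-type mixtures differ, planting ground-truth neighborhoods for
  clustering-recovery tests.

:func:`attach_metadata` adds donor/region/condition columns and can inject
an additive shift on one neighborhood's percentage in "case" donors,
enabling calibration and power studies of the cohort tests. All generators
are bit-reproducible given (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError

ANCHOR_LABEL = "endothelial cell"


@dataclass(frozen=True)
class DistanceLaw:
    """Radial distance law of one cell type relative to the vasculature.

    families: ``fixed`` (constant distance ``scale``), ``uniform``
    (annulus between ``low`` and ``high``), ``exponential`` (mean
    ``scale``). All parameters in μm.
    """

    family: str
    scale: float = 0.0
    low: float = 0.0
    high: float = 0.0

    def __post_init__(self) -> None:
        if self.family not in {"fixed", "uniform", "exponential"}:
            raise ConfigError(f"unknown distance-law family {self.family!r}")
        if self.family == "uniform":
            if not (0 <= self.low < self.high):
                raise ConfigError("uniform law needs 0 <= low < high")
        elif self.scale <= 0:
            raise ConfigError(f"{self.family} law needs a positive scale")

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        if self.family == "fixed":
            return np.full(n, self.scale)
        if self.family == "uniform":
            return rng.uniform(self.low, self.high, n)
        return rng.exponential(self.scale, n)


@dataclass
class VesselTissueConfig:
    """Vessel-anchored tissue: extent in μm, vessel polylines, anchor
    density per μm of vessel length, cell counts and distance laws per
    type, and Gaussian placement noise (μm)."""

    extent: tuple[float, float] = (1000.0, 1000.0)
    z_extent: float | None = None
    vessels: list = field(
        default_factory=lambda: [
            [(100.0, 100.0), (900.0, 300.0)],
            [(100.0, 600.0), (500.0, 900.0), (900.0, 700.0)],
            [(500.0, 100.0), (300.0, 900.0)],
        ]
    )
    anchor_density: float = 0.1
    anchor_label: str = ANCHOR_LABEL
    cell_types: dict = field(
        default_factory=lambda: {
            "t cell": (DistanceLaw("exponential", scale=20.0), 1500),
            "macrophage": (DistanceLaw("uniform", low=10.0, high=80.0), 1000),
            "fibroblast": (DistanceLaw("fixed", scale=40.0), 800),
        }
    )
    noise_sd: float = 2.0

    def __post_init__(self) -> None:
        if self.extent[0] <= 0 or self.extent[1] <= 0:
            raise ConfigError("extent must be positive")
        if self.anchor_density <= 0:
            raise ConfigError("anchor_density must be > 0")
        if not self.vessels:
            raise ConfigError("vessel skeleton is empty but anchor_density > 0")


def _polyline_segments(vessels, dim: int):
    starts, ends = [], []
    for polyline in vessels:
        pts = np.asarray(polyline, dtype=float)
        if pts.shape[1] < dim:
            pts = np.column_stack([pts, np.zeros((len(pts), dim - pts.shape[1]))])
        starts.append(pts[:-1, :dim])
        ends.append(pts[1:, :dim])
    starts = np.concatenate(starts)
    ends = np.concatenate(ends)
    lengths = np.linalg.norm(ends - starts, axis=1)
    return starts, ends, lengths


def _sample_on_skeleton(rng, starts, ends, lengths, n: int):
    """n points uniform by arc length over all segments; returns the points
    and the index of the segment each lies on."""
    cum = np.cumsum(lengths)
    u = rng.uniform(0, cum[-1], n)
    seg = np.searchsorted(cum, u)
    offset = u - (cum[seg] - lengths[seg])
    t = (offset / lengths[seg])[:, None]
    return starts[seg] + t * (ends[seg] - starts[seg]), seg


def skeleton_distance(points: np.ndarray, vessels) -> np.ndarray:
    """Exact distance from each point to the nearest vessel polyline."""
    points = np.asarray(points, dtype=float)
    starts, ends, lengths = _polyline_segments(vessels, points.shape[1])
    d = ends - starts  # (m, dim)
    dd = (d * d).sum(axis=1)
    dd[dd == 0] = 1.0
    # (n, m) projection parameter, clamped to the segment
    t = np.clip(((points[:, None, :] - starts[None]) * d[None]).sum(-1) / dd[None], 0, 1)
    proj = starts[None] + t[..., None] * d[None]
    return np.linalg.norm(points[:, None, :] - proj, axis=-1).min(axis=1)


def _normal_directions(rng, tangents: np.ndarray) -> np.ndarray:
    """Unit directions perpendicular to each local vessel tangent (uniform
    over the normal space), so a sampled radial distance IS the distance to
    the vessel for interior points: in 2D a random side of the vessel, in
    3D a uniform angle around the vessel axis."""
    n, dim = tangents.shape
    t = tangents / np.linalg.norm(tangents, axis=1, keepdims=True)
    if dim == 2:
        side = rng.choice([-1.0, 1.0], n)
        return np.column_stack([-t[:, 1], t[:, 0]]) * side[:, None]
    # 3D: orthonormal basis {u, v} of the plane normal to each tangent
    helper = np.where(np.abs(t[:, [0]]) < 0.9, [[1.0, 0.0, 0.0]], [[0.0, 1.0, 0.0]])
    u = np.cross(t, helper)
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    v = np.cross(t, u)
    phi = rng.uniform(0, 2 * np.pi, n)[:, None]
    return np.cos(phi) * u + np.sin(phi) * v


def generate_vessel_tissue(config: VesselTissueConfig, seed: int):
    """Generate (cells, truth) for vessel-anchored tissue.

    Anchors: Poisson count per polyline (density × arc length), positions
    uniform by arc length. Non-anchors: a vessel point uniform by arc
    length, a direction uniform over the normal space of the local tangent,
    a radial distance from the type's law, plus isotropic Gaussian noise.
    ``truth`` records, per cell, the sampled radial distance (its
    generating law) and the exact distance to the nearest vessel skeleton —
    radial placement can land a cell nearer to a different vessel or
    segment, so the two may differ.
    """
    rng = np.random.default_rng(seed)
    dim = 3 if config.z_extent is not None else 2
    starts, ends, lengths = _polyline_segments(config.vessels, dim)

    n_anchors = int(rng.poisson(config.anchor_density * lengths.sum()))
    anchor_pos, _ = _sample_on_skeleton(rng, starts, ends, lengths, n_anchors)

    positions = [anchor_pos]
    labels = [config.anchor_label] * n_anchors
    radial = [np.zeros(n_anchors)]
    law_names = ["anchor"] * n_anchors
    for type_label, (law, n_cells) in config.cell_types.items():
        base, seg = _sample_on_skeleton(rng, starts, ends, lengths, n_cells)
        r = law.sample(rng, n_cells)
        pos = base + r[:, None] * _normal_directions(rng, (ends - starts)[seg])
        if config.noise_sd > 0:
            pos = pos + rng.normal(0, config.noise_sd, pos.shape)
        positions.append(pos)
        labels.extend([type_label] * n_cells)
        radial.append(r)
        law_names.extend([law.family] * n_cells)

    coords = np.concatenate(positions)
    radial = np.concatenate(radial)
    cells = pd.DataFrame(
        {"cell_id": np.arange(len(coords)), "x": coords[:, 0], "y": coords[:, 1]}
    )
    if dim == 3:
        cells["z"] = coords[:, 2]
    cells["label_original"] = labels
    truth = pd.DataFrame(
        {
            "cell_id": cells["cell_id"],
            "label": labels,
            "law": law_names,
            "radial_distance": radial,
            "skeleton_distance": skeleton_distance(coords, config.vessels),
            "zone": pd.NA,
        }
    )
    return cells, truth


@dataclass
class PlantedZone:
    """Axis-aligned rectangular zone with a cell-type mixture."""

    rect: tuple[float, float, float, float]  # x0, y0, x1, y1
    mixture: dict
    n_cells: int

    def __post_init__(self) -> None:
        x0, y0, x1, y1 = self.rect
        if not (x1 > x0 and y1 > y0):
            raise ConfigError("zone rectangle must have positive area")
        total = sum(self.mixture.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigError(f"zone mixture sums to {total}, expected 1")
        if self.n_cells <= 0:
            raise ConfigError("zone must contain at least one cell")


@dataclass
class PlantedConfig:
    """Planted-neighborhood tissue: disjoint zones, each drawing labels
    from its own mixture. Anchors are sprinkled in all zones by including
    the anchor label in every mixture."""

    zones: list
    anchor_label: str = ANCHOR_LABEL

    def __post_init__(self) -> None:
        rects = [z.rect for z in self.zones]
        for i, a in enumerate(rects):
            for b in rects[i + 1:]:
                if a[0] < b[2] and b[0] < a[2] and a[1] < b[3] and b[1] < a[3]:
                    raise ConfigError(f"zones overlap: {a} and {b}")


def default_planted_config(n_cells: int = 10_000, anchor_fraction: float = 0.15) -> PlantedConfig:
    """Three vertical-strip zones over a 1500 × 1000 μm field with
    total-variation-separated mixtures (TV = 0.55) sharing a common anchor
    fraction, the regime under which clustering recovery is guaranteed."""
    other = 1.0 - anchor_fraction
    types = ("t cell", "epithelial cell", "fibroblast")
    zones = []
    per_zone = n_cells // 3
    for i, dominant in enumerate(types):
        mixture = {ANCHOR_LABEL: anchor_fraction}
        for t in types:
            mixture[t] = other - 2 * (other * 2 / 17) if t == dominant else other * 2 / 17
        # dominant ≈ 0.65, minors = 0.10 each when anchor_fraction = 0.15
        zones.append(
            PlantedZone(rect=(i * 500.0, 0.0, (i + 1) * 500.0, 1000.0), mixture=mixture,
                        n_cells=per_zone)
        )
    return PlantedConfig(zones=zones)


def generate_planted_neighborhoods(config: PlantedConfig, seed: int):
    """Generate (cells, truth): uniform positions within each zone, labels
    drawn from the zone's mixture; ``truth.zone`` records the planted zone
    id for every cell (the recovery ground truth for anchors)."""
    rng = np.random.default_rng(seed)
    frames, zone_ids, labels = [], [], []
    for zid, zone in enumerate(config.zones):
        x0, y0, x1, y1 = zone.rect
        xy = rng.uniform([x0, y0], [x1, y1], size=(zone.n_cells, 2))
        zone_labels = rng.choice(
            sorted(zone.mixture), p=[zone.mixture[k] for k in sorted(zone.mixture)],
            size=zone.n_cells,
        )
        frames.append(xy)
        zone_ids.extend([zid] * zone.n_cells)
        labels.append(zone_labels)
    coords = np.concatenate(frames)
    labels = np.concatenate(labels)
    cells = pd.DataFrame(
        {
            "cell_id": np.arange(len(coords)),
            "x": coords[:, 0],
            "y": coords[:, 1],
            "label_original": labels,
        }
    )
    truth = pd.DataFrame(
        {
            "cell_id": cells["cell_id"],
            "label": labels,
            "law": "planted",
            "radial_distance": np.nan,
            "skeleton_distance": np.nan,
            "zone": np.asarray(zone_ids),
        }
    )
    return cells, truth


@dataclass
class MetadataScheme:
    """Donor/region/condition assignment with optional effect injection.

    Cells are partitioned uniformly at random into ``n_donors`` donors and
    ``n_regions`` regions per donor; the first ``n_case_donors`` (by donor
    index) form the "case" condition arm. When ``region_classes`` is set
    (e.g. ``("sb", "cl")``), regions alternate between the classes. If the
    table has a ``neighborhood`` column, ``shift_points`` (percentage
    points, additive, applied to case donors) and ``donor_effect_sd``
    (donor-level random effect, points) perturb the share of
    ``shift_neighborhood`` by relabeling a matching number of that donor's
    anchors, recording each donor's injected delta in the truth dict.
    """

    n_donors: int = 8
    n_regions: int = 8
    n_case_donors: int = 0
    condition_labels: tuple[str, str] = ("case", "control")
    region_classes: tuple[str, ...] | None = None
    shift_neighborhood: str | None = None
    shift_points: float = 0.0
    donor_effect_sd: float = 0.0


def attach_metadata(cells: pd.DataFrame, scheme: MetadataScheme, seed: int):
    """Populate donor/region/condition metadata; returns (cells, truth).

    ``truth`` maps donor id → injected percentage-point delta on the target
    neighborhood (0 when no effect was requested).
    """
    rng = np.random.default_rng(seed)
    out = cells.copy()
    n = len(out)
    donors = [f"donor{d:02d}" for d in range(scheme.n_donors)]
    donor_assignment = rng.integers(0, scheme.n_donors, n)
    region_assignment = rng.integers(0, scheme.n_regions, n)
    out["donor_id"] = np.asarray(donors)[donor_assignment]
    out["region"] = [f"region{r:02d}" for r in region_assignment]
    out["dataset_id"] = out["donor_id"] + "_" + out["region"]
    case = {donors[d] for d in range(scheme.n_case_donors)}
    out["condition"] = np.where(
        out["donor_id"].isin(case), scheme.condition_labels[0], scheme.condition_labels[1]
    )
    if scheme.region_classes:
        classes = list(scheme.region_classes)
        out["subregion"] = [classes[r % len(classes)] for r in region_assignment]

    injected = {d: 0.0 for d in donors}
    if scheme.shift_neighborhood is not None and "neighborhood" in out.columns:
        names = sorted(out["neighborhood"].unique())
        for donor in donors:
            delta = rng.normal(
                scheme.shift_points if donor in case else 0.0, scheme.donor_effect_sd
            )
            injected[donor] = float(delta)
            rows = np.flatnonzero((out["donor_id"] == donor).to_numpy())
            n_move = int(round(abs(delta) / 100.0 * len(rows)))
            if n_move == 0 or len(names) < 2:
                continue
            in_target = out["neighborhood"].iloc[rows] == scheme.shift_neighborhood
            if delta < 0:
                pool = rows[in_target.to_numpy()]
                others = [m for m in names if m != scheme.shift_neighborhood]
                chosen = rng.choice(pool, size=min(n_move, len(pool)), replace=False)
                out.loc[out.index[chosen], "neighborhood"] = rng.choice(others, size=len(chosen))
            else:
                pool = rows[~in_target.to_numpy()]
                chosen = rng.choice(pool, size=min(n_move, len(pool)), replace=False)
                out.loc[out.index[chosen], "neighborhood"] = scheme.shift_neighborhood
    return out, injected


def simulate_cohort(
    n_donors: int = 16,
    n_case_donors: int = 8,
    n_regions: int = 8,
    anchors_per_region: int = 50,
    neighborhoods: tuple[str, ...] = ("immune enriched", "follicle", "smooth muscle"),
    base_probs: tuple[float, ...] = (0.3, 0.4, 0.3),
    shift_points: float = 0.0,
    donor_effect_sd: float = 4.0,
    seed: int = 0,
) -> pd.DataFrame:
    """One simulated cohort of anchors with neighborhood labels + metadata.

    Anchors draw neighborhood labels i.i.d. from ``base_probs``; donors,
    regions and condition arms are attached and an additive shift of
    ``shift_points`` percentage points on the first neighborhood is
    injected into case donors (donor-level random effect
    ``donor_effect_sd``). Used for calibration/power studies of the cohort
    tests without regenerating spatial tissue.
    """
    rng = np.random.default_rng(seed)
    n = n_donors * n_regions * anchors_per_region
    cells = pd.DataFrame(
        {
            "cell_id": np.arange(n),
            "x": rng.uniform(0, 1000, n),
            "y": rng.uniform(0, 1000, n),
            "label_original": ANCHOR_LABEL,
            "neighborhood": rng.choice(list(neighborhoods), p=list(base_probs), size=n),
        }
    )
    scheme = MetadataScheme(
        n_donors=n_donors,
        n_regions=n_regions,
        n_case_donors=n_case_donors,
        shift_neighborhood=neighborhoods[0],
        shift_points=shift_points,
        donor_effect_sd=donor_effect_sd,
    )
    cells, _ = attach_metadata(cells, scheme, seed=int(rng.integers(2**31)))
    return cells
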