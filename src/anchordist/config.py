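"""Run configuration shared across pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import ValidationError

#: Default maximum nearest-anchor linkage distance, in micrometers.
DEFAULT_MAX_DISTANCE = 200.0

#: Default KNN window size for anchor-centric neighborhoods.
DEFAULT_K_NEIGHBORS = 50

#: Default initial k-means cluster count before manual merging.
DEFAULT_N_CLUSTERS = 20

#: Default concentric KNN window sizes for radial analysis.
DEFAULT_WINDOW_SIZES = (5, 10, 30, 50, 100, 300)


@dataclass
class RunConfig:
    """Parameters of a full pipeline run.

    Attributes
    ----------
    anchor_label
        Cell-type label defining anchor cells (e.g. ``"endothelial cell"``).
    level
        Typology level at which ``anchor_label`` is matched
        (``original``/``l1``/``l2``/``l3``).
    max_distance_threshold
        Maximum retained linkage distance in μm (default 200).
    pixel_size
        μm per pixel applied when reading coordinates (default 1.0).
    k_neighbors
        Neighborhood window size (default 50).
    n_clusters_initial
        Initial k-means cluster count (default 20).
    window_sizes
        Concentric window sizes for radial analysis.
    random_seed
        Seed for all stochastic stages.
    """

    anchor_label: str = "endothelial cell"
    level: str = "l1"
    max_distance_threshold: float = DEFAULT_MAX_DISTANCE
    pixel_size: float = 1.0
    k_neighbors: int = DEFAULT_K_NEIGHBORS
    n_clusters_initial: int = DEFAULT_N_CLUSTERS
    window_sizes: tuple[int, ...] = DEFAULT_WINDOW_SIZES
    random_seed: int = 0

    def __post_init__(self) -> None:
        if self.level not in {"original", "l1", "l2", "l3"}:
            raise ValidationError(f"unknown typology level {self.level!r}")
        if not self.max_distance_threshold > 0:
            raise ValidationError("max_distance_threshold must be > 0")
        if not self.pixel_size > 0:
            raise ValidationError("pixel_size must be > 0")
        if self.k_neighbors < 1:
            raise ValidationError("k_neighbors must be >= 1")
        ws = tuple(int(w) for w in self.window_sizes)
        if any(w <= 0 for w in ws) or any(b <= a for a, b in zip(ws, ws[1:])):
            raise ValidationError("window_sizes must be strictly increasing positive ints")
        self.window_sizes = ws
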