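import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from anchordist import (
    apply_crosswalk,
    load_synthetic_crosswalk,
    select_anchors,
)
from anchordist.synthetic import (
    default_planted_config,
    generate_planted_neighborhoods,
)


@pytest.fixture(scope="session")
def crosswalk():
    return load_synthetic_crosswalk()


@pytest.fixture(scope="session")
def planted():
    """Small planted-neighborhood tissue (3 zones, 3,000 cells), harmonized."""
    cells, truth = generate_planted_neighborhoods(default_planted_config(3000), seed=11)
    cells = apply_crosswalk(cells, load_synthetic_crosswalk())
    return cells, truth


@pytest.fixture(scope="session")
def planted_anchors(planted):
    cells, _ = planted
    return select_anchors(cells, "endothelial cell", "l2")


def random_cells(rng, n, dim=2, extent=100.0, anchor_fraction=0.2):
    """Uniform random cell table with a fraction of anchor-labeled cells."""
    coords = rng.uniform(0, extent, size=(n, dim))
    labels = np.where(
        rng.uniform(size=n) < anchor_fraction, "endothelial cell", "t cell"
    )
    cells = pd.DataFrame({"cell_id": np.arange(n), "x": coords[:, 0], "y": coords[:, 1]})
    if dim == 3:
        cells["z"] = coords[:, 2]
    cells["label_original"] = labels
    return cells
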