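"""KNN composition, clustering, merging, radial analysis, enrichment."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from anchordist import (
    cluster_compositions,
    ec_enrichment,
    knn_neighbor_composition,
    merge_clusters,
    neighborhood_percentages,
    normalized_ec_enrichment,
    radial_composition,
    select_anchors,
    suggest_merges,
)
from anchordist.errors import MappingError, SchemaError, SizeError
from anchordist.neighborhoods import NeighborhoodModel

from conftest import random_cells


def grid_cells(labels, spacing=10.0):
    """Cells on a line with the given original labels."""
    n = len(labels)
    return pd.DataFrame(
        {
            "cell_id": range(n),
            "x": np.arange(n) * spacing,
            "y": 0.0,
            "label_original": labels,
        }
    )


class TestKnnComposition:
    def test_single_label_gives_one_hot_rows(self):
        cells = random_cells(np.random.default_rng(0), 60, anchor_fraction=1.0)
        sel = select_anchors(cells, "endothelial cell", "original")
        comp = knn_neighbor_composition(cells, sel, k=10, level="original")
        assert (comp["endothelial cell"] == 1.0).all()

    def test_rows_sum_to_one_and_nonnegative(self, planted, planted_anchors):
        cells, _ = planted
        comp = knn_neighbor_composition(cells, planted_anchors, k=30, level="l3")
        assert (comp.to_numpy() >= 0).all()
        np.testing.assert_allclose(comp.sum(axis=1), 1.0, atol=1e-9)

    def test_matches_brute_force_knn_on_toy(self):
        rng = np.random.default_rng(4)
        cells = random_cells(rng, 30, extent=50.0)
        cells.loc[0, "label_original"] = "endothelial cell"
        sel = pd.Series(False, index=cells.index)
        from anchordist.distance import AnchorSelection

        mask = np.zeros(30, dtype=bool)
        mask[0] = True
        anchors = AnchorSelection("endothelial cell", "original", mask)
        comp = knn_neighbor_composition(cells, anchors, k=4, level="original")
        # brute force: sort every other cell by distance to the anchor
        p = cells[["x", "y"]].to_numpy()
        d = np.linalg.norm(p - p[0], axis=1)
        nearest = np.argsort(d)[1:5]
        expected = cells["label_original"].iloc[nearest].value_counts(normalize=True)
        for label, frac in expected.items():
            assert comp.iloc[0][label] == pytest.approx(frac)

    def test_center_excluded_from_own_window(self):
        # 1 anchor among non-anchors: with k=3 its own label must not appear
        cells = grid_cells(["a", "b", "b", "b", "b"])
        from anchordist.distance import AnchorSelection

        anchors = AnchorSelection("a", "original", np.array([True] + [False] * 4))
        comp = knn_neighbor_composition(cells, anchors, k=3, level="original")
        assert comp.iloc[0]["b"] == 1.0

    def test_column_marginals_match_counted_neighbor_frequencies(self, planted, planted_anchors):
        cells, _ = planted
        k = 25
        comp = knn_neighbor_composition(cells, planted_anchors, k=k, level="l3")
        from anchordist.distance import coordinates
        from anchordist.neighborhoods import _knn_indices

        idx = _knn_indices(coordinates(cells), np.flatnonzero(planted_anchors.mask), k)
        counted = (
            pd.Series(cells["label_l3"].to_numpy()[idx.ravel()]).value_counts(normalize=True)
        )
        marginal = comp.mean(axis=0)
        for label, frac in counted.items():
            assert marginal[label] == pytest.approx(frac, abs=1e-12)

    def test_k_exceeding_cell_count_raises(self):
        cells = grid_cells(["a", "b", "b"])
        sel = select_anchors(cells, "a", "original")
        with pytest.raises(SizeError):
            knn_neighbor_composition(cells, sel, k=3, level="original")

    def test_zero_anchors_empty_matrix(self):
        cells = grid_cells(["b", "b", "b", "b"])
        sel = select_anchors(cells, "a", "original")
        comp = knn_neighbor_composition(cells, sel, k=2, level="original")
        assert comp.empty


@pytest.fixture(scope="module")
def archetypes():
    """Two far-separated composition archetypes."""
    rng = np.random.default_rng(21)
    a = rng.dirichlet([50, 1, 1], size=40)
    b = rng.dirichlet([1, 1, 50], size=40)
    matrix = pd.DataFrame(
        np.vstack([a, b]), columns=["x", "y", "z"],
        index=pd.Index(range(80), name="cell_id"),
    )
    labels = np.array([0] * 40 + [1] * 40)
    return matrix, labels


class TestClustering:
    def test_separable_mixture_perfect_split(self, archetypes):
        matrix, truth = archetypes
        model = cluster_compositions(matrix, n_clusters=2, seed=0)
        assert adjusted_rand_score(truth, model.assignments) == 1.0

    def test_same_seed_identical_assignments(self, archetypes):
        matrix, _ = archetypes
        a = cluster_compositions(matrix, n_clusters=4, seed=123)
        b = cluster_compositions(matrix, n_clusters=4, seed=123)
        pd.testing.assert_series_equal(a.assignments, b.assignments)

    def test_too_few_rows_raises(self, archetypes):
        matrix, _ = archetypes
        with pytest.raises(SizeError):
            cluster_compositions(matrix.head(3), n_clusters=5, seed=0)

    def test_identity_merge_keeps_clusters(self, archetypes):
        matrix, _ = archetypes
        model = cluster_compositions(matrix, n_clusters=4, seed=0)
        merged = merge_clusters(model, {c: str(c) for c in model.cluster_ids})
        assert (merged.final_labels == model.assignments.astype(str)).all()

    def test_merged_sizes_are_additive(self, archetypes):
        matrix, _ = archetypes
        model = cluster_compositions(matrix, n_clusters=4, seed=0)
        sizes = model.assignments.value_counts()
        merge_map = {0: "A", 1: "A", 2: "B", 3: "B"}
        merged = merge_clusters(model, merge_map)
        counts = merged.final_labels.value_counts()
        assert counts["A"] == sizes[0] + sizes[1]
        assert counts["B"] == sizes[2] + sizes[3]

    def test_20_clusters_merged_to_11_names(self):
        rng = np.random.default_rng(2)
        matrix = pd.DataFrame(
            rng.dirichlet(np.ones(5), 400), index=pd.Index(range(400), name="cell_id")
        )
        model = cluster_compositions(matrix, n_clusters=20, seed=0)
        merge_map = {c: f"NB{c % 11}" for c in model.cluster_ids}
        merged = merge_clusters(model, merge_map)
        assert merged.final_labels.nunique() == 11

    def test_partial_merge_map_lists_missing_ids(self, archetypes):
        matrix, _ = archetypes
        model = cluster_compositions(matrix, n_clusters=4, seed=0)
        with pytest.raises(MappingError, match="3"):
            merge_clusters(model, {0: "A", 1: "A", 2: "B"})


class TestSuggestMerges:
    def test_identical_centroids_interleaved_positions_merged(self):
        rng = np.random.default_rng(8)
        cells = random_cells(rng, 200, anchor_fraction=1.0, extent=100.0)
        sel = select_anchors(cells, "endothelial cell", "original")
        matrix = pd.DataFrame(
            rng.dirichlet([30, 30], 200), columns=["p", "q"],
            index=pd.Index(cells["cell_id"], name="cell_id"),
        )
        # force two clusters with statistically identical centroids
        assignments = pd.Series(rng.integers(0, 2, 200), index=matrix.index)
        model = NeighborhoodModel(k_initial=2, seed=0, assignments=assignments)
        merge_map = suggest_merges(model, matrix, cells=cells, anchors=sel)
        assert len(set(merge_map.values())) == 1

    def test_orthogonal_one_hot_centroids_not_merged(self):
        matrix = pd.DataFrame(
            np.repeat(np.eye(3), 20, axis=0), columns=["a", "b", "c"],
            index=pd.Index(range(60), name="cell_id"),
        )
        assignments = pd.Series(np.repeat([0, 1, 2], 20), index=matrix.index)
        model = NeighborhoodModel(k_initial=3, seed=0, assignments=assignments)
        merge_map = suggest_merges(model, matrix)
        assert len(set(merge_map.values())) == 3

    def test_overclustered_planted_pair_collapses_to_truth(self):
        rng = np.random.default_rng(31)
        a = rng.dirichlet([60, 2, 2], 100)
        b = rng.dirichlet([2, 2, 60], 100)
        matrix = pd.DataFrame(np.vstack([a, b]), columns=["x", "y", "z"],
                              index=pd.Index(range(200), name="cell_id"))
        model = cluster_compositions(matrix, n_clusters=4, seed=0)
        merge_map = suggest_merges(model, matrix)
        merged = merge_clusters(model, merge_map)
        truth = np.array([0] * 100 + [1] * 100)
        assert adjusted_rand_score(truth, merged.final_labels) == 1.0


@pytest.fixture(scope="module")
def fitted(planted, planted_anchors):
    cells, _ = planted
    matrix = knn_neighbor_composition(cells, planted_anchors, k=30, level="l3")
    model = cluster_compositions(matrix, n_clusters=6, seed=0)
    model = merge_clusters(model, suggest_merges(model, matrix, n_target=3))
    return cells, planted_anchors, matrix, model


class TestRadialAndEnrichment:
    def test_radial_at_clustering_window_reproduces_matrix_means(self, fitted):
        cells, anchors, matrix, model = fitted
        radial = radial_composition(cells, anchors, model, window_sizes=[10, 30], level="l3")
        expected = matrix.groupby(model.final_labels).mean()
        for name in model.neighborhood_names:
            got = radial.loc[(name, 30)][expected.columns]
            np.testing.assert_array_equal(got.to_numpy(float), expected.loc[name].to_numpy())

    def test_radial_rows_sum_to_one(self, fitted):
        cells, anchors, _, model = fitted
        radial = radial_composition(cells, anchors, model, window_sizes=[5, 20], level="l3")
        np.testing.assert_allclose(radial.sum(axis=1), 1.0, atol=1e-9)

    def test_enrichment_saturation_and_absence(self):
        # pure anchor tissue -> enrichment 1; anchors far from others -> 0
        rng = np.random.default_rng(3)
        pure = random_cells(rng, 50, anchor_fraction=1.0)
        sel = select_anchors(pure, "endothelial cell", "original")
        matrix = knn_neighbor_composition(pure, sel, k=5, level="original")
        model = NeighborhoodModel(
            k_initial=1, seed=0,
            assignments=pd.Series(0, index=matrix.index), merge_map={0: "all"},
        )
        assert ec_enrichment(pure, sel, model, k=5)["all"] == 1.0

        mixed = pure.copy()
        mixed.loc[mixed.index[1:], "label_original"] = "t cell"
        sel1 = select_anchors(mixed, "endothelial cell", "original")
        model1 = NeighborhoodModel(
            k_initial=1, seed=0,
            assignments=pd.Series(0, index=[mixed.loc[0, "cell_id"]]), merge_map={0: "all"},
        )
        assert ec_enrichment(mixed, sel1, model1, k=5)["all"] == 0.0

    def test_enrichment_matches_hand_counted_tallies(self):
        # two anchors on a line; k=2 windows are hand-countable
        cells = grid_cells(["a", "a", "b", "b", "b"], spacing=1.0)
        from anchordist.distance import AnchorSelection

        mask = np.array([True, True, False, False, False])
        sel = AnchorSelection("a", "original", mask)
        model = NeighborhoodModel(
            k_initial=2, seed=0,
            assignments=pd.Series([0, 1], index=pd.Index([0, 1], name="cell_id")),
            merge_map={0: "left", 1: "right"},
        )
        out = ec_enrichment(cells, sel, model, k=2)
        # anchor 0 neighbors: cells 1,2 -> 1 anchor of 2; anchor 1: cells 0,2 -> 1 of 2
        assert out["left"] == 0.5 and out["right"] == 0.5

    def test_normalized_enrichment_planted_ratio(self):
        """An anchor-dense zone at 2x the tissue background gives fold ~2."""
        rng = np.random.default_rng(12)
        n = 4000
        x = rng.uniform(0, 1000, n)
        y = rng.uniform(0, 500, n)
        dense = x < 500
        p = np.where(dense, 0.3, 0.0)
        labels = np.where(rng.uniform(size=n) < p, "endothelial cell", "t cell")
        cells = pd.DataFrame(
            {"cell_id": np.arange(n), "x": x, "y": y, "label_original": labels,
             "donor_id": "d0", "subregion": "tissue"}
        )
        sel = select_anchors(cells, "endothelial cell", "original")
        ids = cells["cell_id"].to_numpy()[sel.mask]
        model = NeighborhoodModel(
            k_initial=1, seed=0,
            assignments=pd.Series(0, index=pd.Index(ids, name="cell_id")),
            merge_map={0: "dense"},
        )
        out = normalized_ec_enrichment(cells, sel, model, k=50)
        assert out.loc[0, "fold_change"] == pytest.approx(2.0, abs=0.2)

    def test_missing_subregion_column_raises(self, fitted):
        cells, anchors, _, model = fitted
        with pytest.raises(SchemaError):
            normalized_ec_enrichment(cells, anchors, model, k=10)


class TestNeighborhoodPercentages:
    def test_single_neighborhood_is_100_percent_everywhere(self, planted, planted_anchors):
        cells, _ = planted
        cells = cells.copy()
        cells["region"] = np.where(cells["x"] < 500, "west", "east")
        ids = cells["cell_id"].to_numpy()[planted_anchors.mask]
        model = NeighborhoodModel(
            k_initial=1, seed=0,
            assignments=pd.Series(0, index=pd.Index(ids, name="cell_id")),
            merge_map={0: "only"},
        )
        out = neighborhood_percentages(model, cells, "region")
        assert (out["only"] == 1.0).all()

    def test_counting_oracle_3_of_10(self):
        cells = grid_cells(["a"] * 10)
        cells["region"] = "r0"
        from anchordist.distance import AnchorSelection

        model = NeighborhoodModel(
            k_initial=2, seed=0,
            assignments=pd.Series([0] * 3 + [1] * 7, index=pd.Index(range(10), name="cell_id")),
            merge_map={0: "A", 1: "B"},
        )
        out = neighborhood_percentages(model, cells, "region")
        assert out.loc["r0", "A"] == pytest.approx(0.3)

    def test_rows_sum_to_one_per_group(self, planted, planted_anchors):
        cells, truth = planted
        cells = cells.copy()
        cells["region"] = np.where(cells["y"] < 500, "south", "north")
        ids = cells["cell_id"].to_numpy()[planted_anchors.mask]
        rng = np.random.default_rng(1)
        model = NeighborhoodModel(
            k_initial=3, seed=0,
            assignments=pd.Series(rng.integers(0, 3, len(ids)),
                                  index=pd.Index(ids, name="cell_id")),
            merge_map={0: "A", 1: "B", 2: "C"},
        )
        out = neighborhood_percentages(model, cells, "region")
        np.testing.assert_allclose(out.sum(axis=1), 1.0, atol=1e-9)
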