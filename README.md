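# anchordist

Cell-to-nearest-anchor-cell distance graphs and anchor-centric
neighborhood analysis for spatial single-cell data.

## What it is for

Spatial omics assays (CODEX, CyCIF, Xenium, MIBI-TOF, GeoMx, ...) produce
tables of cell centroids with cell-type labels. A recurring question in
tissue biology is how every other cell type is organized *relative to one
anchor cell type* — canonically vascular endothelial cells (ECs), because
proximity to blood vessels governs oxygen and nutrient access. This
package, aimed at computational biologists working with segmented
spatial datasets, provides that analysis end to end:

* **Distance graph** — for each non-anchor cell *i* with centroid
  xᵢ ∈ ℝ² or ℝ³ and anchor set *A*, one edge
  (i, argmin_{a∈A} ‖xᵢ − x_a‖₂) kept when the distance is ≤ dₘₐₓ
  (default 200 μm), computed exactly via a k-d tree.
* **Label harmonization** — raw labels → a 3-level typology
  (L3 specific → L1, a fixed 8-category vocabulary) + Cell Ontology
  annotation via a curated crosswalk CSV.
* **Distance distributions** — n, mean, sd, median, quartiles, IQR and
  CV = 100·sd/μ per cell type × region/condition/donor.
* **EC-centric neighborhoods** — per anchor, the composition vector
  p ∈ Δ^(L−1) of its k = 50 nearest cells; k-means (20 initial clusters)
  → merged, named neighborhoods; radial analysis over windows of
  5–300 cells; EC enrichment of each neighborhood normalized per donor by
  its subregion's EC fraction (fold change).
* **Cohort statistics** — donor-level neighborhood percentages tested
  with unpaired (Welch) t-tests across conditions, paired t-tests across
  tissue classes, and OLS against covariates such as BMI.
* **Synthetic tissue** — generators with known ground truth
  (vessel-anchored distance laws, planted neighborhood zones, donor
  metadata with injected effects) so every stage is testable without
  external data.

## Worked example

```python
import anchordist as ad
from anchordist.synthetic import default_planted_config, generate_planted_neighborhoods
from sklearn.metrics import adjusted_rand_score

# 10,000-cell tissue with 3 planted zones of distinct composition
cells, truth = generate_planted_neighborhoods(default_planted_config(10_000), seed=1)
cells = ad.apply_crosswalk(cells, ad.load_synthetic_crosswalk())

anchors = ad.select_anchors(cells, "endothelial cell", "l2")   # 1544 anchors
edges = ad.nearest_anchor_edges(cells, anchors, max_distance=200.0)
print(ad.summarize_distances(edges, cells, level="l2")
        [["cell_type", "n", "median", "iqr", "cv"]].round(2))
```

```
      cell_type    n  median   iqr    cv
epithelial cell 2787   14.45 10.87 52.89
     fibroblast 2794   15.04 11.51 52.65
         t cell 2874   14.12 10.67 53.06
```

Every non-anchor type sits a median ~14–15 μm from its nearest EC — as
expected here, since all types are sprinkled uniformly around the same
anchor density; in real tissue these medians separate perivascular from
distal cell types.

```python
matrix = ad.knn_neighbor_composition(cells, anchors, k=50, level="l3")
model = ad.cluster_compositions(matrix, n_clusters=20, seed=1)
model = ad.merge_clusters(
    model, ad.suggest_merges(model, matrix, cells=cells, anchors=anchors, n_target=3))
zone = truth.set_index("cell_id").loc[model.assignments.index, "zone"]
print(model.final_labels.value_counts().to_dict())
print(round(adjusted_rand_score(zone, model.final_labels), 3))
```

```
{'N2': 524, 'N1': 512, 'N0': 508}
0.973
```

The 20 k-means clusters, merged down to 3 suggested neighborhoods,
recover the three planted zones almost perfectly (adjusted Rand index
0.973); each neighborhood holds about a third of the 1,544 anchors, and
`ad.ec_enrichment(...)` reports EC fractions ≈ 0.15 in each — the
planted anchor share.

The same pipeline is available from a shell:

```bash
anchordist simulate --mode planted --n-cells 10000 --seed 1 -o nodes.csv
anchordist harmonize -i nodes.csv --crosswalk crosswalk.csv -o cells.csv
anchordist distances -i cells.csv --anchor "endothelial cell" --level l2 \
    --max-dist 200 -o edges.csv
anchordist neighborhoods -i cells.csv --anchor "endothelial cell" --level l2 \
    --k 50 --clusters 20 --seed 1 --suggest 3 -o assignments.csv
anchordist enrich -i cells.csv --assignments assignments.csv \
    --anchor "endothelial cell" --level l2 -o enrichment.csv
```

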