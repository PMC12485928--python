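# Methods

## Overview

`anchordist` quantifies tissue architecture in spatial single-cell data
(CODEX, CyCIF, Xenium, MIBI-TOF, GeoMx, ...) through the lens of a single
*anchor* cell type — by default vascular endothelial cells (ECs). Its
stages are:

1. **I/O and units.** Cell tables (`nodes.csv`: x, y, optional z,
   cell-type name, one row per cell) are read with case-insensitive header
   matching; coordinates are multiplied by the pixel size on read and kept
   in micrometers only — no raw-pixel state survives parsing. When the
   file carries no id column, `cell_id` is the 0-based row index, so
   linkages are traceable back to file rows. Cells with blank labels are
   kept under the label `unknown` rather than dropped, because *unknown*
   is a first-class category of the typology.
2. **Harmonization.** Raw labels are normalized (lower-cased, whitespace
   collapsed) and joined against an expert-curated crosswalk that assigns
   each original label a three-level typology — L3 (most specific), L2,
   L1 (most general; a closed 8-category vocabulary: endothelial,
   epithelial, hematopoietic precursor, immune, mesenchymal, neural,
   mixed immune/epithelial, unknown) — plus a Cell Ontology label/ID and
   a match level (`exactMatch` or `narrowMatch`). Matching is performed on
   normalized labels so crosswalk files may use any casing. Only
   casing/whitespace normalization is applied; orthographic variants
   (hyphen vs space) must be resolved in the crosswalk itself.
3. **Distance graph.** Every non-anchor cell is linked to its nearest
   anchor by exact Euclidean distance (2D or 3D), retained when the
   distance is at most the maximum distance threshold (default 200 μm).
4. **Distribution statistics.** Per cell type and grouping: n, mean, sd,
   median, quartiles, IQR and CV = 100·sd/mean.
5. **EC-centric neighborhoods.** Per anchor, the k = 50 nearest cells
   define a composition vector over cell-type labels; k-means (20 initial
   clusters) groups anchors into microenvironments, which are merged into
   named neighborhoods; radial analysis recomputes compositions at
   windows of 5, 10, 30, 50, 100, 300 cells; EC enrichment is normalized
   per donor by the enclosing subregion's EC fraction.
6. **Cohort statistics.** Neighborhood percentages per image/region are
   averaged per donor (donors are the replicates) and tested: unpaired
   t-test between condition groups, paired t-test between tissue classes
   within donors, OLS against continuous covariates.

## Numerical contracts and tie-breaking

* **Exact nearest neighbors.** The production path uses a k-d tree
  (`scipy.spatial.cKDTree`); approximate search is deliberately excluded
  so that the all-pairs brute-force scan (`brute_force_nearest`) is an
  exact oracle, not an approximation check. Both paths compute the final
  distance with the same `sqrt(sum((a-b)^2))` formula, so their outputs
  agree to the last bit and are asserted equal, not merely close.
* **Ties** (several anchors exactly equidistant from a cell) are broken
  by the lowest anchor `cell_id`. The tree path re-examines all anchors
  within a hair (1 + 1e-9 relative) of the nearest reported distance and
  applies the same rule, making output independent of tree layout.
* **Threshold comparison is inclusive** (distance ≤ threshold retained):
  "within 200 μm" is read inclusively and frozen for bit-stable outputs.
* **Anchor cells receive no edges**; anchor-to-anchor distances are out
  of contract. Zero selected anchors yields an empty edge table plus a
  logged warning, not an exception.
* **Quartiles** use linear interpolation on sorted values (the numpy
  default); **sd** uses the n−1 denominator; **CV** is reported in
  percent. These conventions are frozen choices — reported medians/IQRs
  depend on them only in the last decimals.
* **KNN windows** are neighbor-count windows, not metric radii. The
  center anchor is excluded from its own window; anchor-type cells do
  count as neighbors (EC fractions inside EC neighborhoods are
  meaningful). Composition rows therefore sum to 1 exactly (up to float
  addition, ≤ 1e-9).
* **K-means** runs on raw fraction vectors (all features share one scale,
  so no standardization), k-means++ init, 10 restarts, tolerance 1e-4,
  seeded — bit-reproducible per seed.
* **Merging is user-driven.** The published 20 → 11 merge of EC clusters
  was a judgment call based on composition and spatial co-localization;
  `suggest_merges` quantifies that judgment (centroid cosine similarity ≥
  0.9 AND spatial co-occurrence ≥ 0.25 among 10 nearest anchors, greedy
  agglomeration; or merge-to-`n_target` when an explicit target is given)
  but is advisory: the user-supplied merge map is authoritative, and its
  thresholds are tool parameters, not claims about any dataset.
* **Radial consistency.** At a window equal to the clustering k, radial
  analysis recomputes the same compositions, so per-neighborhood means
  reproduce the clustering matrix exactly (asserted with exact equality).
* **Enrichment** is computed per anchor (fraction of anchor-type cells in
  its window), then averaged per neighborhood — per-anchor-then-averaged,
  not pooled. Normalization divides by the anchor-type fraction of all
  cells in the same donor × subregion; zero-background records are
  flagged and carry no number.
* **Cohort tests**: Welch's unequal-variance form is the default for the
  unpaired test (pooled variance available via `equal_var=True`); all
  tests are two-sided; no multiple-testing correction by default (an
  optional Benjamini–Hochberg helper is provided). The paired test equals
  a one-sample t-test on per-donor differences; region values are
  averaged within donor × class first, so region order is irrelevant.
  Degenerate cases are handled explicitly: identical groups give t = 0,
  p = 1; zero-variance nonzero differences are flagged degenerate with
  p → 0 rather than raising.

## Synthetic tissue generator

The generator emulates the statistical structure the analyses assume,
with known ground truth:

* **Vessel-anchored tissue.** Anchors are a Poisson process along vessel
  polylines (density per μm of arc length); each non-anchor cell samples
  a vessel point uniformly by arc length, a direction uniform over the
  *normal space of the local tangent*, and a radial distance from its
  type's law (`fixed`, `uniform` annulus, or `exponential`; parameters in
  μm), plus isotropic Gaussian jitter (default sd 2 μm). Sampling the
  direction perpendicular to the vessel is essential: it makes the
  sampled radius equal the cell's true distance to a straight vessel, so
  configured distance laws are recoverable from measured edges
  (exponential scale 20 μm ⇒ median 20·ln 2 ≈ 13.86 μm at high anchor
  density). Truth records both the sampled radius and the exact
  nearest-skeleton distance, which differ near corners or other vessels.
  Defaults (1000 × 1000 μm field, three polyline vessels, anchor density
  0.1/μm, exponential/uniform/fixed laws at 20/10–80/40 μm for
  t cells/macrophages/fibroblasts) are a priori choices of a plausible
  microanatomy scale — a capillary-bed-like spacing where most cells lie
  within ~100 μm of vasculature.
* **Planted neighborhoods.** Disjoint rectangular zones each draw labels
  i.i.d. from their own mixture; anchors appear in every zone (shared
  anchor fraction 0.15). The default three-zone configuration uses
  dominant-type mixtures (0.65/0.10/0.10 + anchors) with pairwise total
  variation 0.55 — the separated regime in which full-pipeline recovery
  (50-NN, 20 clusters, merge to 3) achieves ARI ≥ 0.9. Residual
  disagreement comes from anchors within a window radius (~40 μm at
  10,000 cells) of zone borders, whose windows genuinely mix zones.
* **Metadata and effects.** Donors/regions are uniform random partitions;
  condition arms are donor-level. Effect injection relabels a donor's
  anchors to shift one neighborhood's percentage by a donor-specific
  draw N(shift, donor_sd) in percentage points, recording realized
  deltas. The cohort calibration design — 16 donors (8 per arm), 8
  regions × 50 anchors each, base shares (0.3, 0.4, 0.3), donor random
  effect sd 4 points, −10-point injected shift — was fixed a priori as a
  realistic donor-level dispersion for neighborhood percentages; it gives
  the t-test its nominal 5% size and >0.8 power at 8 donors/arm.

What the generator does **not** emulate: cell-cell exclusion (it is a
Poisson-like process, real cells cannot overlap), branching vascular
morphogenesis, segmentation error, label noise correlated with position,
and anisotropic section geometry. Passing tests therefore demonstrate the
*algorithms'* correctness and calibration under their stated assumptions,
not biological fidelity of any particular tissue.

## Problem sizes

The validation suite and `scripts/acceptance.py` use: 100+ random
instances (n ≤ 500) for oracle equivalence; 10,000 cells for planted
recovery and enrichment; 5,000 cells for distance-law recovery; 1,000
null and 200 power cohort replicates; and a 20,000-cell tissue for
end-to-end CLI determinism. These sizes give Monte-Carlo error well
inside every asserted tolerance while keeping the whole suite under a
minute of compute for the heavy parts.

## Known limitations

* The paired/unpaired tests assume approximate normality of donor-level
  percentages; with very few donors (< 5 per arm) the t-approximation is
  fragile, and no non-parametric fallback is provided.
* Crosswalk entries must be curated externally; the package validates
  structure (closed L1 vocabulary, match levels, conflicting duplicates)
  but cannot infer mappings.
* Serial-section stacks without a true z coordinate should be analyzed as
  separate 2D tables; the package treats any complete z column as true 3D.
* `suggest_merges` is O(c² · anchors) per agglomeration round — fine for
  tens of clusters, not intended for hundreds.
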