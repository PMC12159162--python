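# Methods

This note documents the models, conventions and numerical choices behind
`gangliostat`, in the order the pipeline runs them.

## Synthetic tissue: the zonated cluster process

`simulate_ganglion` generates one section as a superposition of per-type
parent–offspring (Thomas-type) cluster processes inside a convex outline
(default: regular 24-gon of radius 500 µm, the scale of a DRG section).

* **Parents.** The expected number of cluster parents per type is Poisson
  with mean `parent_intensity` (default 8, floor 1). Each parent is placed
  along a ray from the polygon centroid at a uniform angle; its *normalized
  edge depth* d (0 = on the boundary, 1 = at the centroid) is drawn from
  Beta(c·q, c·(1−q)) with target quantile q = `depth_quantile` and
  concentration c = `depth_concentration` (default 20). Depth along a ray is
  monotone in d for any convex outline, which is all the zonation ordering
  statistics consume. The Beta family was chosen because it is the simplest
  bounded unimodal family parameterized directly by a mean position and a
  sharpness; no generative zonation model exists to copy, only measured
  depth distributions, so these defaults are descriptive placeholders
  rather than estimates.
* **Offspring.** Cells are attached to uniformly chosen parents and scattered
  isotropically with Gaussian SD `dispersion_um` (default 25 µm — the scale
  of a few somata). Offspring falling outside the tissue are redrawn
  (vectorized rejection, 200 rounds, then collapsed onto the parent), so
  containment is exact by construction, not approximately enforced.
* **Volumes.** Lognormal per type (default meanlog 6, sdlog 0.3, i.e. median
  ≈ 400 volume units with ±30% spread). Only the ratio structure matters to
  the volume-normalized distances; no distributional form is claimed for
  real somata.

Every generator draws from a named CRC-32-keyed substream of one top-level
seed, so adding a component never perturbs another's stream and identical
(config, seed) give byte-identical outputs.

**What the generator does not emulate:** transcript-level noise,
segmentation errors, anisotropic or concave tissue, 3-D structure, and
density gradients other than radial zonation. Passing tests therefore
demonstrate correctness of the *statistics*, not robustness to real
segmentation artifacts.

## Spatial proximity

Distances are plain Euclidean on centroids; normalization divides by the
mean of the two cell volumes, making the normalized distance unit-bearing
(µm per volume unit) — no further rescaling is applied. The type matrix
averages normalized distances over all between-type pairs; within-type
diagonals exclude self-pairs, whose zero distances would deflate the mean.
A type with a single cell gets a missing (NaN) diagonal rather than a fake
zero. With several sections the matrix is computed per section and pooled by
unweighted mean, since no principled per-section weights exist.

The **neighbor score** is 1 − (d − min)/(max − min) over all finite entries
of the type matrix: a pure re-expression of the distances that uses no
quantity beyond them, invariant to affine rescaling. A k-nearest-neighbor
composition score (`knn_neighbor_score`, the fraction of each type's k
nearest neighbors belonging to the other type, symmetrized) is provided as a
pluggable alternative for users who prefer a neighborhood-composition
reading; the distance-derived score is the default and the one the tests
characterize.

Type dendrograms use average-linkage agglomeration on the type matrix
treated directly as dissimilarities (scipy linkage on the condensed form,
types presented in lexicographic order so ties resolve deterministically).

## Edge zonation

The boundary is the convex hull of *all* cells in a section — neuronal and
non-neuronal together — because peripheral glia define the physical edge as
much as neurons do; a user-supplied GeoJSON polygon overrides this. Hull
vertices are a subset of input centroids; collinear inputs are a hard error.
Distances use shapely's exact point-to-ring distance; exterior query points
(possible only with user polygons) get their positive ring distance plus a
warning instead of an error.

## Module architecture

* **Assignment.** "Within 95% of the row maximum" is implemented closed
  (≥ 0.95·R_max) so the argmax always satisfies its own rule and
  exact-boundary ties are included. The 0.3 floor applies to every member.
* **Eigengene.** First principal component of the member genes standardized
  across cells, scaled to unit variance, sign-fixed to correlate
  non-negatively with the module's mean expression profile (the WGCNA
  convention). Zero-variance member genes are a hard error listing the
  offenders.
* **Magnitudes.** Groups with a single cell contribute no SD; they are
  excluded from the SD mean with a warning. A zero mean SD with nonzero
  magnitude leaves the relative magnitude NaN (flagged) rather than
  infinite.
* **Selection.** A module is kept iff cluster relative magnitude ≥ 3.7 *and*
  it exceeds the dataset relative magnitude. The second clause is this
  package's operationalization of excluding batch-driven modules; both
  values are always reported so users can re-filter under a different rule.
* **Digitization.** Positions are measured from the *minimum* cluster mean,
  p = (mean − min)/magnitude, because eigengene means can be negative and an
  absolute reading of "33% of the magnitude" would then be ill-defined. The
  middle bin is closed at both ends ([1/3, 2/3] → 0.5). Magnitude below 1e-9
  is degenerate: all levels 0, flagged via `attrs["degenerate"]`.
* **Width/uniqueness.** w_max defaults to the observed maximum width;
  passing `w_max=10` pins the scale to the conventional constant.
* **Gene-set score.** 24 average-expression bins (rank-based cut, so tied
  averages still spread evenly), 100 control genes per set gene drawn with
  replacement from the matching bin, seeded through the substream mechanism;
  score = set mean − pooled control mean per cell.
* **Dot scores.** All three per-type vectors are min–max scaled to [0, 1];
  a constant vector scales to all zeros with a warning (no 0/0). The TF
  statistic is accepted as either mean expression or percent-expressing —
  the scaling makes the pipeline agnostic.

## Set enrichment

One-sided enrichment p = P(X ≥ k) for X ~ Hypergeometric(N, K, n); overlap 0
gives p = 1 exactly. The default universe is the union of all module and
regulon genes; a modules-only or user universe is selectable, with
out-of-universe genes either a hard error or dropped with a warning.
Benjamini–Hochberg runs across **all** grid cells jointly — per-row
adjustment would make significance depend on how many regulons a module
happens to face. A two-sided Fisher option is exposed.

The null-calibration benchmark uses universe 800, module 80, regulon 80:
large enough that the discrete hypergeometric support is fine-grained (the
largest attainable level below 0.05 is ≈ 0.045), so the empirical rate of
p ≤ 0.05 is expected inside the binomial band around 0.05 rather than far
below it, as it would be for tiny sets.

## Consensus labeling and cross-similarity

The classifier behind `train_and_score` is an interface: any object with
`fit`/`predict_proba`/`classes_` plugs in. The default is a regularized
multinomial linear model with normalized-exponential outputs — the pipeline
logic (min–max feature scaling fitted on the reference, probabilistic
scores, 0.55 cutoff on the argmax score, consensus across sources) is the
reproducible content, not any particular model family. The 0.55 cutoff is
applied to the maximum class score. Cell-cycle or other unwanted genes are
excluded via a user-supplied list; no built-in gene catalog is shipped.

`cross_similarity` concatenates all datasets' score profiles, takes the top
15 principal components (clamped to the feature count when profiles are
narrow), and builds a 100-NN graph in that space. The published procedure
uses the neighbor graph to "construct" the type-pair metric without a
formula; here the graph **gates** comparability: a type pair receives the
Pearson correlation of its type-mean PC profiles only if at least one
neighbor edge connects cells of the two groups, and ungated pairs are
floored to the minimum of the full correlation matrix (flooring to the
minimum of the *gated* entries would degenerate when all gated pairs are
highly similar). The sign-preserving power transform |s|^1.25·sign(s) and
column z-scoring (population SD) produce the final matrix; a constant
column is left at 0 after centering, with a warning.

## Problem sizes

The validation benchmarks run at sizes chosen to make the planted effects
unambiguous while keeping the whole suite fast on a laptop: 3 types × 1000
cells over 20 seeds for zonation; 3 types × 150 cells over 20 seeds for
neighbor scores; 3 modules × 10 clusters × 10 seeds at loading/noise = 5
for digitization; exhaustive Fisher enumeration up to universe 40 plus 1000
null draws for calibration; 300 cells × 3 sources × 20 seeds for consensus;
two 400-cell 4-type datasets × 10 seeds for cross-similarity.

## Known limitations

* The neighbor score is a relative statistic: it orders type pairs within
  one matrix but is not comparable across tissues with different distance
  ranges.
* The boundary is convex by construction; invaginated tissue edges inflate
  edge distances for cells in concavities.
* Digitization inherits the eigengene's sensitivity to module contamination:
  a module mixing two anti-correlated programs can digitize to a profile
  matching neither.
* The kNN-gated correlation is one defensible reading of an underspecified
  published procedure; the gating choice is isolated in one function and
  documented so it can be swapped.
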