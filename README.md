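# gangliostat

Spatial-organization and co-expression-module statistics for in-situ
transcriptomics of sensory ganglia.

Imaging-based spatial transcriptomics (MERFISH/MERSCOPE-class assays) yields,
per tissue section, a table of segmented cells with centroid coordinates,
volumes and type labels, next to a gene × cell expression matrix. For a
structure like the dorsal root ganglion (DRG), two organizational questions
follow immediately: *which cell types sit near which* (spatial proximity),
and *which types occupy the periphery versus the core* (zonation relative to
the tissue edge). On the expression side, co-expression network analysis
(WGCNA-style) produces module eigengenes and a gene × module correlation
(kME) table whose post-processing — which genes belong to which modules, how
module activity distributes over neuron types, how unique each module's
activity pattern is, and which gene-regulatory programs (eRegulons) its
members overlap — defines the transcriptional architecture of cell identity.
Integrating several independently annotated single-cell atlases finally
requires harmonizing nomenclatures, keeping only cells on which classifiers
trained on every source dataset agree, and quantifying cross-dataset
cell-type similarity.

`gangliostat` implements these statistics as a tested Python library with a
thin CLI, together with synthetic-data generators that plant known ground
truth (zonation depths, module levels, set overlaps, label concordance) so
every stage can be validated end to end without any real dataset.

## The statistics

**Volume-normalized type distance.** For cells *i*, *j* with centroids
(xᵢ, yᵢ) and volumes vᵢ,

d<sub>ij</sub> = √((xᵢ−xⱼ)² + (yᵢ−yⱼ)²),  d<sub>ij,norm</sub> = d<sub>ij</sub> / ((vᵢ+vⱼ)/2).

Averaging d<sub>ij,norm</sub> over all cell pairs of types (A, B) — within-type
self-pairs excluded — gives the type-distance matrix; the **neighbor score**
is its min–max inversion, 1 for the closest type pair and 0 for the farthest.

**Edge zonation.** The tissue boundary is the convex hull of all centroids
in a section; each cell gets its shortest Euclidean distance to the hull
ring, summarized per type (mean, median, quartiles) and ranked from
periphery inward.

**Module architecture.** Given a kME table, a gene with row maximum R_max is
assigned to its best module and, redundantly, to every module with
kME ≥ 0.95·R_max, subject to a floor of 0.3. Per module, the eigengene
(first principal component of the standardized member genes) is summarized
by cluster and by dataset; *magnitude* = max − min of cluster means, and
*relative magnitude* divides by the mean within-group SD. Modules with
cluster relative magnitude ≥ 3.7 that is not dominated by the dataset
relative magnitude are kept. Cluster means are digitized onto {0, 0.5, 1}
by thirds of the min–max range; *signal width* is the row sum of levels and
*uniqueness* = w_max − width (w_max = 10 by convention, or the observed
maximum). Identity bar plots decompose each cluster into (assigned gene
count × level) segments. Per-cell gene-set scores use expression-bin-matched
control genes; regulator dot scores multiply min–max-scaled TF expression by
the scaled region-set score.

**Set enrichment.** Module × regulon overlaps are tested with the one-sided
Fisher exact (hypergeometric tail) test and Benjamini–Hochberg adjusted
across the whole grid; modules without any significant overlap are flagged.

**Consensus labeling.** Source labels are harmonized through a homology map;
a cell is kept only if all sources agree (exempt families — e.g. A-LTMRs —
need only family-level agreement). A pluggable probabilistic classifier
(default: regularized multinomial linear model on min–max-scaled marker
features) scores query cells; assignments below a 0.55 score cutoff become
`unassigned`. Concatenated score profiles are embedded with PCA (top 15
PCs); a 100-nearest-neighbor graph gates which type pairs receive the
Pearson correlation of their type-mean PC profiles, which is then
power-transformed (power 1.25) and column z-scored into the cross-dataset
type-similarity matrix.

## Worked example

```python
from gangliostat.synthetic import GanglionConfig, simulate_ganglion
from gangliostat.spatial import type_distance_matrix, neighbor_score
from gangliostat.zonation import edge_distances, edge_summary

cfg = GanglionConfig(
    cells_per_type=[400, 400, 400],
    depth_quantile=[0.15, 0.5, 0.85],   # SGC peripheral, PEP deep
    type_names=["SGC", "NP", "PEP"],
)
cells, boundary, truth = simulate_ganglion(cfg, seed=7)

summary = edge_summary(edge_distances(cells, boundary=boundary))
print(summary[["cell_type", "n", "mean", "median", "rank_peripheral"]].round(1))
```

```
cell_type   n  mean  median  rank_peripheral
      SGC 400  61.2    48.6                1
       NP 400 298.0   289.8                2
      PEP 400 423.4   431.0                3
```

The planted depth quantiles (0.15 / 0.5 / 0.85) come back as the peripheral
ranking: satellite-glia-like cells hug the edge (mean 61 µm from the
boundary), peptidergic cells sit deepest (423 µm).

```python
tdm = type_distance_matrix(cells)     # volume-normalized, µm per volume unit
print(neighbor_score(tdm).round(2))
```

```
       NP   PEP   SGC
NP   0.74  0.71  0.08
PEP  0.71  1.00  0.11
SGC  0.08  0.11  0.00
```

Within-type entries dominate (PEP–PEP scores 1.00, the closest pairing in
the matrix) because each type is laid down as a clustered point process —
the same co-localization signal the neighbor score is designed to expose in
real sections.

The same stages are available from the shell:

```bash
gangliostat simulate ganglion --config ganglion.yaml --seed 7 --outdir sim/
gangliostat zonation --cells sim/cells.csv --out results/zon
gangliostat spatial  --cells sim/cells.csv --out results/spa
```

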