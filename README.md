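# matsne — structure-preserving t-SNE for matrix-framed data

Many datasets are indexed by a row label and a column label at once, and
every cell holds an object: subjects × skeleton joints with a 3-D motion
trajectory per cell, patients × genes with an expression value per cell,
regions × years with a histogram of daily temperatures per cell.  We call
these *matrix-framed* data.  Flattening them and running an ordinary
embedding discards the frame: the margin with the larger distances
dominates the neighborhoods and the other margin's group structure
disappears from the map.

`matsne` embeds every (row, column) element as a 2-D point Y_ik by
minimizing a convex combination of two KL divergences,

    C(Y) = α · KL(P^r ‖ Q^r) + (1 − α) · KL(P^c ‖ Q^c),

where P^r and P^c are Gaussian affinities built from row-margin and
column-margin distances with *independently* perplexity-calibrated
bandwidths, and Q^r, Q^c are Student-t affinities on aggregated embedding
distances (Σ_k ‖Y_ik − Y_jk‖² between rows, Σ_i ‖Y_ik − Y_il‖² between
columns).  The two calibrated perplexities make the method insensitive to
scale differences between margins.  α = 1 and α = 0 are exactly classical
t-SNE on one margin; interior α preserves both.

The weight is chosen by a cluster-separability criterion: marginal runs
give cluster counts G1 (rows) and G0 (columns) as the smallest K-means
partition with SSB/SST > 0.9; their cross-product defines G = G0·G1
element classes; α* maximizes the separability of those classes over a
grid in (0, 1).  ARI/NMI scoring is available as an alternative.

Three element kinds are built in, with the matching margin distances:
scalars (Euclidean), multivariate time series (per-coordinate dynamic time
warping, `symmetric1`/`symmetric2` step patterns), and histograms
(closed-form L2-Wasserstein between piecewise-uniform densities).  A
classical unstructured-distance t-SNE on the flattened elements is included
as the comparison baseline, and planted-structure generators for all three
kinds provide ground-truthed synthetic benchmarks.

## Worked example

```python
from sklearn.metrics import adjusted_rand_score
from matsne import OptimizerConfig, PlantedDesign, make_scalar_data, matrix_tsne
from matsne.selection import kmeans_labels

design = PlantedDesign.balanced(20, 18, R=2, C=3, separation=10, noise_sd=1, seed=0)
data, design = make_scalar_data(design)

embedding, trace = matrix_tsne(data, OptimizerConfig(alpha=0.88, iterations=1000, seed=0))
pred = kmeans_labels(embedding.points(), g=6, seed=0)
print(adjusted_rand_score(design.cross_labels(), pred))
```

Running `python examples/01_scalar_biclustering.py` (the same computation
with reporting) prints:

```
embedded 360 elements (20 rows × 18 columns)
KL cost: 0.9946 initial -> 0.0286 final
cross-product ARI (K-means with G=6 vs planted truth): 1.000
```

360 points is one per matrix element; the KL cost dropping from 0.99 to
0.03 shows the optimizer matched the low-dimensional neighbor
distributions to the high-dimensional ones; ARI 1.000 means K-means on the
embedding recovers the planted 2×3 row-group × column-group checkerboard
exactly.

The other scripts in `examples/` each demonstrate one capability: weight
selection (`02`), DTW margins on time-series cells (`03`), Wasserstein
margins on histogram cells (`04`), and the scale-mismatch regime where the
unstructured baseline loses a margin and the structured embedding does not
(`05`).

A thin CLI wraps the same library calls:

```sh
matsne simulate --kind scalar --out-dir work/
matsne select-alpha work/data.csv --out-dir work/
matsne embed work/data.csv --alpha 0.84 --out-dir work/
matsne baseline work/data.csv --out-dir work/
matsne evaluate work/data.csv work/truth.json --out-dir work/
```

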