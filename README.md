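# panoview

Iterative clustering of single-cell RNA-seq expression matrices with a
convex-hull density-peak core (a reimplementation of the PanoView / OLMC
algorithm), together with the Gaussian-blob simulators and the rare-cell
benchmark harness needed to reproduce its headline simulation results
without any external data.

## The problem

Clustering a genes × cells expression matrix is the first step of most
scRNA-seq analyses, and it is hard for two reasons: results are often very
sensitive to non-intuitive input parameters, and cell types differ widely in
both abundance and internal variability, so density-based methods with one
global density scale either dissolve rare subpopulations into their large
neighbours or shred large, loose clusters. `panoview` is for analysts who
want major and rare cell types detected *simultaneously* with default
parameters.

## The method

Two ideas are combined.

**OLMC (Ordering Local Maximum by Convex hull)** clusters a low-dimensional
point cloud (here, cells in 3-D PCA space). All pairwise distances are
histogrammed into *B<sub>c</sub>* = 20 bins and the bin interval becomes the
neighborhood radius *R<sub>c</sub>*; each cell's local density is its
neighbor count within *R<sub>c</sub>*, ranking cells *P*₁ … *P*<sub>N</sub>.
The first group is seeded from the first of *B<sub>g</sub>* equal-width bins
of the distance-to-*P*₁ histogram and its convex hull *H*₁ is built. Walking
down the density ranking, the next unassigned cell *P*<sub>m</sub> joins the
group minimizing its distance *R*<sub>Pm</sub><sup>H</sup> to the nearest
hull vertex among groups where *R*<sub>Pm</sub><sup>H</sup> <
*R̄*<sub>H</sub> (the mean pairwise distance of that hull's vertices),
expanding that hull; otherwise *P*<sub>m</sub> is a new local maximum and
seeds its own group. The search ends when no hull can be constructed from
what remains, and every leftover cell is assigned to the nearest peak.
*B<sub>g</sub>* is chosen by a saturation scan (increase by 5 until the
number of maxima stops changing, ceiling 100) whenever the cloud has fewer
than 1000 cells.

**The iterative outer loop** re-selects dispersion-variable genes
(z-score > 1.5 within 20 mean-expression bins, mean ≥ 0.5), embeds the
current cells in a fresh 3-PC space, clusters with OLMC, and measures each
cluster's tightness as σ², the variance of within-cluster pairwise
correlation distances *x*<sub>i,j</sub> = 1 − corr(*v*<sub>i</sub>,
*v*<sub>j</sub>). The Gini index of the top-*i* variances,
G = ΣΣ|σ<sub>i</sub>² − σ<sub>j</sub>²| / (2n²μ), gates the loop: while any
G<sub>i</sub> > 0.05 the lowest-variance ("mature") cluster is frozen and
its cells removed; when all G<sub>i</sub> < 0.05 the surviving clusters join
the frozen ones. Finally, clusters whose centroids join below 20% of the
maximum height of an average-linkage correlation-distance dendrogram are
merged.

The eight user-facing knobs and their defaults: `zscore 1.5`,
`gene_low 0.5`, `gini 0.05`, `bc 20`, `bg 20`, `maxbb 20`,
`cell_number 1000`, `fclust_height 0.2`.

## Worked example

```python
from panoview import (BlobConfig, RareConfig, generate_rare,
                      cluster_cells, rare_outcome, adjusted_rand_index)

cfg = RareConfig(base=BlobConfig(n_centers=10, cluster_sd=1.0, seed=1))
E, truth, rare_label = generate_rare(cfg)   # 455 cells x 20,000 genes
part, trace = cluster_cells(E)              # default parameters

pred = part.labels_for(E.cell_ids)
out = rare_outcome(truth, rare_label, pred)
print(f"cells: {E.n_cells}, clusters found: {part.n_clusters}")
print(f"iterations: {len(trace)}; mature sizes: "
      f"{[t.mature_size for t in trace if t.mature_size]}")
print(f"rare cluster ({out.rare_truth_size} cells) recovered exactly: {out.recovered}")
print(f"false-positive rare type: {out.false_positive}")
print(f"ARI vs ground truth: {adjusted_rand_index(truth, pred):.3f}")
```

prints

```
cells: 455, clusters found: 10
iterations: 3; mature sizes: [5, 50]
rare cluster (5 cells) recovered exactly: True
false-positive rare type: False
ARI vs ground truth: 1.000
```

This dataset has ten Gaussian clusters of 50 cells, one down-sampled to 5
cells (1.1% of the population). The engine froze the 5-cell rare cluster and
one major cluster as mature in its first two iterations, stopped at the
third, and the final partition matches the ground truth exactly — including
the rare subpopulation, which is counted as recovered only under strict set
equality.

The same run from a shell:

```bash
panoview simulate rare --n-centers 10 --seed 1 --outdir data/
panoview run --input data/matrix.csv --outdir results/
```

which writes `clusters.tsv` (cell, cluster label, iteration found) and
`iterations.tsv` (the per-iteration log).

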