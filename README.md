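# satkit

**Has a single-cell RNA-seq experiment sampled enough cells?** `satkit`
answers this by downsampling a UMI count matrix into nested subsets,
re-clustering every subset, scoring how well the full analysis' clusters
survive, and issuing a regression-based saturation verdict.

## Who this is for

Designers of cell-atlas experiments and analysts of droplet scRNA-seq data
who need an empirical answer to "would more cells change my clustering?" —
especially when rare populations (< 1% of cells) are the scientific target.

## The method

Given a genes × cells count matrix (10x MTX directory or 10x HDF5):

1. **QC** — remove cells with > 10% mitochondrial or > 10% ribosomal UMI
   content, or fewer than 1000 detected genes.
2. **Cluster** — normalize each cell to 10,000 counts, log1p, center and
   scale genes, PCA (50 components), keep the components whose eigenvalues
   exceed the Marchenko–Pastur noise edge, build a shared-nearest-neighbor
   graph (k = 10, edges weighted by the Jaccard similarity of neighbor
   sets) and partition it with Louvain modularity optimization.
3. **Downsample** — draw nested random subsets by repeated halving
   (each level sampled from the previous, so 101,592 cells halve to
   50,796, then 25,398, ...), uniformly over cells so library composition
   is preserved in expectation.
4. **Score** — for each pair (full analysis, subset analysis), restrict to
   common barcodes and form the cluster × cluster contingency table. For a
   reference cluster *c* with common-cell count *n_c* and overlap counts
   *n_cs* with subset clusters *s*:
   - **preservation**(c) = max_s (n_cs / n_c) — top-down stability;
   - **conservation**(s) = max_c (n_cs / n_s) — the reciprocal, bottom-up;
   - **split**(c) = #{s : n_cs ≥ 1} — distinguishes an even 2-way split
     (preservation 0.5, split 2) from scattering (preservation 0.5, split 10).
   Raw and adjusted Rand indices are reported alongside for comparison.
5. **Complexity index** — cluster centroids in the *reference* PC space are
   joined by average-linkage hierarchical clustering on Euclidean
   distances; the index is the total branch length of that dendrogram
   (0 for one cluster, linear under coordinate scaling).
6. **Saturation verdict** — ordinary least squares of mean preservation
   against subset size (and against complexity), refit while truncating the
   largest sizes one at a time. If the full-data fit has R² < 0.6 and R²
   does not improve as the largest subsets are added back, cluster
   recapitulation no longer depends on cell number: **saturated**.

A negative-binomial simulator with planted hierarchical structure (broad
types → subtypes, exclusive marker genes, mito/ribo gene blocks, latent
within-type gene programs, configurable rare populations) makes the whole
pipeline testable without external data.

## Worked example

Simulate 2,000 cells of five well-separated types, cluster, downsample
through four halving levels twice, and judge saturation:

```python
from satkit.pipeline import run_pipeline

summary = run_pipeline(
    {"simulate": {"n_cells": 2000, "n_genes": 500}, "seed": 7,
     "qc": {"min_genes": 100}, "n_levels": 4, "n_replicates": 2},
    "demo_report",
)
print(summary["verdict"], summary["n_clusters_full"])
```

This prints `saturated 6` and writes per-subset label files, overlap
tables, preservation curves and `report.json` under `demo_report/`. The
first records of the curve show why: halving 1,964 QC-passing cells to 982
and 491 leaves mean preservation at 0.996 and 0.998 — the subsets
reproduce the full clustering almost perfectly — and the R² scan of
preservation vs cell number stays at 0.11–0.13, far below the 0.6
threshold, so adding cells is not changing the result. Deeper levels
(245, 122 cells) start merging clusters (conservation falls to 0.80,
adjusted Rand 0.77) while preservation stays ≥ 0.98: the surviving
clusters are intact, there are just fewer of them.

The same workflow is available from the shell:

```bash
satkit simulate --seed 7 --out sim/
satkit qc --in sim/ --out qc/ --min-genes 100
satkit cluster --in qc/ --k 10 --seed 7 --out labels.tsv
satkit compare --ref sim/truth_labels.tsv --sub labels.tsv --out cmp/
```

## Layout

- `src/satkit/io.py` — 10x MTX/HDF5 readers, label TSVs, overlap CSV
- `src/satkit/qc.py` — QC filter, normalization, PCA, significant PCs
- `src/satkit/cluster.py` — SNN-Jaccard graph, Louvain, iterative reclustering
- `src/satkit/downsample.py` — nested halving and fraction series
- `src/satkit/metrics.py` — overlap, preservation, conservation, split, Rand
- `src/satkit/complexity.py` — complexity index, R² saturation scan
- `src/satkit/markers.py` — Wilcoxon one-vs-rest markers, unique markers
- `src/satkit/simulate.py` — synthetic count matrices with planted truth
- `src/satkit/pipeline.py`, `src/satkit/cli.py` — end-to-end workflow

See `docs/methods.md` for modeling assumptions, parameter defaults and
numerical conventions.
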