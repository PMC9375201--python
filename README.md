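# mcgrain

Metacell coarse-graining for single-cell RNA-seq, with the sample-weighted
statistics needed to analyze the reduced data without forgetting how many
cells each metacell represents.

Single-cell experiments routinely produce 10⁴–10⁶ transcriptomes, most of
which are near-duplicates of other cells of the same state. `mcgrain`
merges transcriptomically similar cells into **metacells**: it embeds
cells with PCA on the most variable genes, connects each cell to its k
nearest neighbors (k = 5 by default), applies the walktrap community
detection algorithm to the resulting graph, and cuts the merge dendrogram
at a user-chosen **graining level**

γ = N_cells / N_metacells,

so γ = 1 is the identity and γ = 10 shrinks the data tenfold. A metacell's
expression profile is the arithmetic mean of its members' log-normalized
expression, and its **size** is the number of cells it contains. Because
the dendrogram is kept, other graining levels can be cut without
recomputing the graph; an approximate mode handles very large datasets by
building metacells on a subsample and assigning the remaining cells to the
nearest metacell centroid.

Downstream, every statistic weights metacell *i* by its size *s_i* — as if
it were *s_i* identical cells:

- **weighted scaling**: per-gene z-scores with weighted mean/variance;
- **weighted PCA**: the SVD of (1/N_c)·XᵀWX with W = diag(s), embedding
  X_PCA = XV;
- **weighted Ward clustering**: each metacell enters the agglomeration as
  a pre-formed group of *s_i* observations;
- **weighted silhouette**: a(i), b(i), s(i) with size-weighted averages
  and the overall S = (1/N_c)·Σ s(i)·s_i;
- **weighted Welch t-test** for one-vs-rest differential expression with
  Benjamini–Hochberg correction, and **weighted Pearson correlation**;
- gene-signature scores (sum of max-normalized expression) and AUC.

Evaluation metrics from the same tradition are included: per-metacell
**purity** (majority-type fraction) and rare-type weighted purity, the
**adjusted Rand index** between clusterings, the **DE recovery rate**
TPR = |M ∩ M̃|/|M|, a **GO match score ratio** for top correlated gene
pairs, and **velocity purity / similarity** for pooled RNA-velocity
fields. A seeded synthetic-data module (negative-binomial counts with
spiked markers and dropout, Gaussian blob data, trajectory velocity
fields, modular GO annotations) makes everything testable offline.

## Worked example

`examples/01_build_metacells.py` simulates five well-separated populations
(2000 cells × 500 genes), builds metacells at γ = 10 and prints:

```
cells: 2000, metacells: 200 (gamma = 10.0)
metacell sizes: min 3, median 9, max 27
median purity (walktrap): 1.000
median purity (random grouping): 0.400
metacell network: 1377 weighted edges
```

A median purity of 1.0 means metacells essentially never mix cell types,
while grouping the same cells at random stays near the largest type
frequency (0.4 here). `examples/03_differential_expression.py` continues
with the spiked-marker count simulation:

```
reference DE set |M| = 124 (124 of them truly spiked)
TPR at gamma=10 (metacells):  1.000
TPR with subsampling to 200 cells: 0.710
```

so the metacell analysis recovers the entire single-cell DE gene set at a
tenth of the size, where subsampling to the same size loses 29% of it.
The other examples cover weighted clustering/silhouette, velocity pooling
and the GO match score.

## Command line

A thin CLI wraps the library for shell pipelines:

```bash
mcgrain simulate --out bundle/ --seed 0
mcgrain coarsen  --input bundle/ --gamma 10 --out partition.tsv
mcgrain profile  --input bundle/ --partition partition.tsv --out profile/
mcgrain dea      --input bundle/ --partition partition.tsv --out de.csv
mcgrain evaluate --metric purity --metric tpr --input bundle/ \
    --partition partition.tsv --labels bundle/labels.tsv --out metrics.csv
```

Matrices follow the 10x convention (Matrix Market with features/barcodes
sidecars, genes as rows); partitions are TSV with a JSON sidecar recording
the full configuration and seed.

## Documentation

`docs/methods.md` describes the model, the weighting conventions, the
synthetic-data generators and the numerical choices in detail.
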