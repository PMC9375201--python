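# Methods

## The coarse-graining model

`mcgrain` treats a single-cell dataset as redundant samples of a smaller
number of transcriptional states and replaces groups of highly similar
cells by their average. The pipeline is:

1. **Log-normalization.** Each cell is scaled to a common total
   (`scale_target`, default 10,000) and transformed with log(1 + x).
   Cells with zero total counts are rejected by name rather than
   silently dropped.
2. **Feature selection.** The `n_hvg` most variable genes (default 1000,
   ties broken by gene index) define the feature space.
3. **PCA.** Genes are centered (not scaled) and the top `n_pcs`
   components (default 10) retained, with each component's sign fixed so
   its largest-magnitude loading is positive. The basis, gene means and
   (optional) scales are stored so new cells can be projected later.
4. **Cell graph.** Each cell is connected to its k = 5 nearest neighbors
   (Euclidean distance in PCA space, distance ties to the lower cell
   index); the directed lists are symmetrized by union. A shared-nearest-
   neighbor mode links cells whose k-neighbor lists have Jaccard overlap
   above 1/15 (configurable).
5. **Community hierarchy.** Walktrap (random-walk length 4) is run per
   connected component, producing a merge dendrogram per component.
6. **Cut.** For a graining level γ, the target metacell count is
   N_SC = round(N_c/γ) (half-up, never below the number of components).
   Cuts are allocated across components proportionally to component size
   by largest-remainder rounding (ties to the larger component), and each
   component's dendrogram is cut by replaying its merge prefix.

Keeping the dendrogram makes exploring several γ cheap. Within a
component, cuts at finer levels always refine coarser ones; across
components the largest-remainder allocation can occasionally reallocate a
metacell when γ changes (the classical apportionment non-monotonicity),
which we accept as a limitation.

Louvain is available as an alternative backend. Because it cannot target
a community count directly, communities are split (via their own walktrap
sub-dendrograms, largest community first) or merged (smallest community
into its most connected neighbor) until exactly N_SC remain; partitions
record which algorithm produced them.

**Approximate mode.** For very large datasets the exact pipeline runs on
a uniform random subsample (`n_subsample`, default 50,000; the seed is
mandatory), targeting round(N_c/γ) metacells; remaining cells are
projected into the subsample's PCA basis and assigned to the metacell
with the nearest centroid. With the subsample equal to the full dataset
this reproduces the exact pipeline bit for bit.

**Annotation-consistent metacells.** `split_by_annotation` splits any
metacell containing more than one label into one metacell per
(metacell, label) pair, so the output refines the input and has label
purity exactly 1. `gamma_for_sample` implements the per-sample graining
rule γ = min(⌊n/20⌋, 10) used when each sample of a multi-sample study is
coarse-grained separately, clamped to ≥ 1 because the printed formula
returns 0 for n < 20, which is not a valid graining level.

## Size-weighted statistics

Every downstream statistic treats metacell i as size(i) cells. Two
weighted-variance conventions exist in the literature; we fix them as
follows and state why:

- **Frequency convention (default for everything):** n = Σw, weighted
  mean m = Σw·x/Σw, variance s² = Σw·(x − m)²/(Σw − 1). With integer
  weights this matches the classical statistic computed on the sample in
  which row i is literally repeated w_i times — the module's central
  correctness oracle, enforced by tests for scaling, PCA, Ward
  clustering, the t-test and Pearson correlation.
- **Reliability convention (option in `weighted_scale`):** variance
  Σŵ(x − μ)²/(1 − Σŵ²) with normalized weights ŵ. This is the convention
  of R's `corpcor::wt.scale`; it reduces to the same unbiased z-score at
  unit weights but differs from the expansion semantics for non-unit
  weights, so it is exposed as `convention="reliability"` rather than
  being the default.

**Weighted PCA** computes the top eigenvectors V of (1/N_c)·XᵀWX for the
(weighted-)scaled profile X and embeds metacells as X_PCA = XV. With
integer weights the embedding coincides with PCA of the row-expanded
matrix restricted to the unique rows.

**Weighted Ward** seeds the agglomeration with each metacell as a
pre-formed group of size(i) observations at its profile coordinates; the
merge cost is the within-cluster sum-of-squares increase
n_u·n_v/(n_u+n_v)·||c_u − c_v||², with centroids and counts updated
exactly. Cost ties are broken by the lower index pair, making the result
deterministic.

**Weighted silhouette.** With |C| the total cell count of cluster C,
a(i) = Σ_{j∈C_m, j≠i} d(i,j)·size(j) / (|C_m| − size(i)) and
b(i) = min_k Σ_{j∈C_k} d(i,j)·size(j) / |C_k|;
s(i) = (b − a)/max(a, b) and S = Σ s(i)·size(i)/N_c. For a cluster
containing a single metacell the denominator of a(i) vanishes regardless
of that metacell's size, so s(i) is defined as 0 for any such cluster
(the singleton rule's natural reading when one metacell stands for many
cells). Distances are Euclidean in the weighted-PCA space by default; a
precomputed distance matrix can be supplied.

**Weighted DE** runs a Welch (unequal-variance) t-test per gene,
one-vs-rest, with frequency-weighted moments and Welch–Satterthwaite
degrees of freedom, followed by Benjamini–Hochberg adjustment across
genes within each comparison; logFC is the difference of weighted means
in log space. Welch rather than pooled variance is the safer default when
group sizes and variances differ. Two flat groups with equal means give
t = 0, p = 1 rather than an error.

*Calibration caveat:* frequency weighting treats member cells as
independent observations. When metacells group genuinely similar cells
this is the intended semantics, but for arbitrary groupings of null data
the within-metacell averaging shrinks the residual variance faster than
the weights acknowledge and p-values become anti-conservative. The null
calibration test therefore checks the test at single-cell resolution
(unit weights), where its assumptions hold exactly.

**Metacell clustering protocol.** Clustering metacells mirrors the
single-cell protocol: select top variable genes (size-weighted variance),
weighted-scale, weighted PCA, weighted Ward. Gene selection is essential,
not cosmetic: after scaling, every noise gene carries unit variance, and
with hundreds of noise genes against 100–200 metacells the top sample
eigenvalues of pure noise exceed the biological ones, burying the signal.
The simulations here use the top 100 of 500 genes — the same order of
selectivity as the common practice of keeping 500–1000 of ~20,000 genes.

## Evaluation metrics

- **Purity**: per metacell, the fraction of cells of its most abundant
  type; the median across metacells summarizes a partition. The
  rare-type variant reports (a) the fraction of rare-type cells landing
  in metacells majority-annotated to that type and (b) their purity
  weighted by the number of rare cells per metacell.
- **ARI**: Hubert–Arabie adjusted Rand index from the contingency table;
  an exhaustive pair-counting oracle over all 203 partitions of six items
  and scikit-learn's implementation cross-check it in tests.
- **DE recovery**: the single-cell reference M is the union over clusters
  of genes with BH-adjusted p < 0.05 and logFC above a threshold (0.5 by
  default; 0.25 suits weaker signals); the metacell set M̃ takes the top
  |M| significant genes ranked by logFC (ties by gene id; shortfalls are
  logged). TPR = |M ∩ M̃|/|M| equals precision because |M̃| = |M|.
- **GO match score ratio**: genes expressed (> 0) in more than half the
  cells enter all-pairs Pearson (single-cell) and weighted Pearson
  (metacell) correlation; per level the top 1000 BH-significant pairs are
  ranked by signed correlation (a magnitude option exists); each pair
  scores the Jaccard coefficient of its GO id sets, and the ratio
  compares metacell-exclusive against single-cell-exclusive pairs.
- **Velocity purity**: max over members x of the median over members y of
  cos(v(x), v(y)) — the median includes y = x and uses the midpoint
  convention for even counts, so two opposite vectors score 0 and a
  singleton metacell scores 1. Cosine with a zero vector is defined as 0.
  **Velocity similarity** is the median over cells of the cosine between
  a cell's vector and its metacell's pooled vector; the subsampling
  counterpart compares each cell to its nearest retained cell.

## Synthetic data

Three seeded generators emulate the statistical features the method
relies on; all are bit-reproducible from an integer seed.

- `simulate_counts`: per-type mean vectors share a gamma-distributed
  baseline; a disjoint block of genes per type (`de_frac`, default 5%) is
  up-shifted by `effect_lfc` (default 2 in natural-log space, a strong
  marker); counts are negative-binomial with dispersion 0.5 (a typical
  scRNA-seq overdispersion) and uniform library sizes (1000–5000),
  followed by independent Bernoulli dropout (default 30%). Disjoint
  marker blocks make ground-truth DE sets unambiguous. Optional
  spliced/unspliced layers are a binomial split of the counts.
- `simulate_blobs`: spherical Gaussian blobs in log-expression space —
  2000 cells, 500 genes, 5 types, 20 informative genes and a center
  separation of 5 within-blob SDs by default — the canonical
  well-separated regime in which metacells must preserve structure
  exactly.
- `simulate_velocity`: unit vectors along a type-ordered trajectory in
  embedding space plus isotropic Gaussian noise; `simulate_go`: module
  genes share module-private GO terms with probability `overlap` plus
  rare background terms, so within-module Jaccard exceeds cross-module.

What the generators do **not** model: batch effects, doublets, ambient
RNA, continuous differentiation manifolds, or gene-length/GC biases.
Passing tests therefore demonstrate correctness of the algorithms and
their weighting semantics, not robustness to every artifact of real data.

## Numerical choices

- kNN search is exact (chunked brute force) with distance ties broken by
  lower index; PCA signs are fixed by the largest-magnitude loading;
  degenerate (constant) genes are zeroed in scaling using a relative
  threshold (sd ≤ 1e-10 × max|x|) so floating-point round-off on constant
  genes cannot leak garbage.
- N_SC rounding is half-up; walktrap steps default to 4 (the algorithm's
  canonical walk length); dendrogram cuts replay merge prefixes through a
  union-find, so identical inputs give identical partitions.
- Majority-vote annotation ties break lexicographically; metacell ids are
  0-based and relabeled by first-cell order everywhere.
- Recommended γ range is 10–50 (a warning is emitted outside it);
  problem sizes in the test-suite simulations (600–2000 cells, 100–500
  genes) were chosen so the full suite exercises every claim on a single
  CPU in about a minute.

## Known limitations

- The weighted t-test's independence assumption makes metacell-level
  p-values optimistic when metacells are heterogeneous (see the
  calibration caveat above); the DE recovery metric, which compares
  rankings rather than error rates, is unaffected.
- Cross-component cut allocation is not monotone in γ (apportionment
  paradox); within components refinement is guaranteed.
- Louvain's γ-matching changes the algorithm's natural community
  structure when N_SC is far from what Louvain would choose.
- The GO match score requires both levels to have exclusive top pairs;
  it errors (rather than returning a meaningless ratio) when the pair
  lists coincide.
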