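# Methods

## The gf-icf model

A UMI count matrix is a genes × cells table of non-negative integers
`f_ij`. Because 3′-tagged UMI counts are free of gene-length bias, the
count of gene *i* in cell *j* plays exactly the role of a word's
occurrence count in a document, and the TF-IDF transform applies
verbatim:

* **Gene frequency.** `GF_ij = f_ij / Σ_k f_kj`. Every cell column sums
  to one, removing depth differences. Requires depth > 0, which QC
  guarantees.
* **Inverse cell frequency.** `ICF_i = log(N / (n_i + 1))` with *N* the
  number of cells and `n_i` the number of cells in which gene *i* has a
  strictly positive count. The log base is natural; any base change is
  a global positive rescaling of all ICFs and cancels in the final L2
  normalization (the depth-invariance test exercises this).
* **Weighting and L2.** `w_ij = GF_ij · ICF_i`, then each cell column
  is divided by its Euclidean norm, so cells are unit vectors and inner
  products are cosine similarities.

Two points of the formula are genuinely open and are exposed as config
options rather than silently fixed:

* `icf_smoothing` — `log(N/(n_i+1))` (default; the standard smoothed
  IDF) vs `log(N/n_i + 1)`. The printed formula is typographically
  ambiguous between the two groupings; the default is the conventional
  one, and both are implemented and tested.
* `allow_negative_icf` — under the default smoothing a gene expressed
  in *every* cell gets `ICF = log(N/(N+1)) < 0`. A negative
  "importance" inverts the meaning of the score, so by default such
  genes are clamped to 0 and flagged (`GficfMatrix.clamped_genes`); the
  literal formula is available behind the flag. With clamping, a gene
  expressed everywhere contributes exactly nothing — the intended
  behavior for housekeeping genes. A cell whose expressed genes all
  have zero ICF cannot be L2-normalized; this degenerate case raises an
  error naming the cells.

`n_i` counts strict positivity, with no threshold. Genes with zero
total count are kept in the matrix (ICF `log(N)`, weight 0 everywhere)
and can be listed via `RawCountMatrix.zero_count_genes()`.

## Quality control

Cells are retained when detected genes ≥ `min_genes` (500), total UMI ≥
`min_umi` (1,500) and mitochondrial UMI fraction ≤ `max_mito_fraction`
(0.10). Boundary cells pass: the filters remove cells *below* the gene
and UMI floors and *above* the mitochondrial ceiling. Mitochondrial
genes are identified by an explicit id set or by id prefix (default
`MT-`/`mt-`); absent mito ids warn rather than fail. QC never removes
genes; a minimum-cells-per-gene filter is deliberately not applied by
default. The filter is idempotent and independent of cell order.

## Dimensionality reduction and embedding

PCA treats cells as observations and gf-icf weights as features, with
gene-wise mean-centering and no variance scaling — the weights are
already on a common scale after L2, and standardizing would re-inflate
the near-constant genes that ICF suppressed. The top 50 components
("meta-genes") are kept. Component signs are fixed by forcing each
component's largest-magnitude loading positive, making scores
reproducible across solvers. The exact solver is used up to 2,000
observations/features, the seeded randomized solver beyond.

t-SNE (scikit-learn, PCA initialization, single job) with seed 0 and
perplexity 30 is the default embedder; UMAP with a fixed `random_state`
is the alternative. Both are delegated to their reference
implementations — they are established tools here, not contributions.
Final coordinates are min-max rescaled per axis to [−1, 1]
independently (a degenerate constant axis maps to 0); per-axis scaling
is the only linear map that attains both bounds on both axes. All
intra-type distances are computed on the rescaled coordinates, so they
are comparable across runs and datasets.

## Graph clustering

From the rescaled 2-D coordinates (clustering in meta-gene space is
available via `cluster_space`, off by default), each cell's k = 50
nearest neighbors under Manhattan distance are computed with the cell
itself excluded; distance ties break by ascending cell index, making
neighbor sets fully deterministic. An undirected edge joins *u* and *v*
whenever one lies in the other's neighbor set, weighted by the Jaccard
coefficient of the two neighbor sets; zero-overlap edges are omitted.
Note the edge-candidate rule means two cells with identical neighbor
sets but outside each other's neighborhoods are *not* joined — the
graph is a weighting of the kNN relation, not an all-pairs similarity
graph. Louvain community detection (igraph's multilevel implementation,
seeded) partitions the graph; isolated cells become singleton clusters,
and labels are renumbered contiguously by first appearance. The
reported modularity is the standard weighted Newman modularity of the
returned partition and is verified in tests against a direct
recomputation from the edge list.

## Signatures and annotation

A cluster's signature is the top 100 genes by summed gf-icf weight over
its cells (ties broken lexicographically; zero-weight genes never
enter). Annotation scores the signature, as a gene set, against one
ranked list per reference cell type. The reference ranking is the
log2 fold-change (pseudo-count 1) of the type's mean expression versus
the mean of all other types in the panel — a discriminative ranking is
required for type-specific calls, and fold-change-vs-rest is the
minimal standard choice. The enrichment score is the classical GSEA
running sum: hits advance by `|stat|^p / Σ_hits |stat|^p` (p = 1 by
default, 0 for the unweighted Kolmogorov–Smirnov form), misses retreat
by `1/(n − m)`, and the ES is the signed maximal deviation. An empty
signature–panel intersection is *undefined* and reported as
`unassigned`, never as 0.

The null model permutes gene labels (equivalently, draws random
position sets of the same size), vectorized so the running-sum extrema
are evaluated only at hit boundaries. NES divides the observed ES by
the mean same-sign null ES; the p-value is the same-sign null tail
fraction with a +1 pseudo-count, which is uniform under the null (the
calibration test checks this with a KS test). Clusters are assigned
the type with the highest NES — not the smallest p-value, which
saturates at `1/(n_permutations+1)` — with ties broken by raw ES, then
type name. Cross-species gene matching is out of scope: panel and
signature must share a gene namespace. Collapsing fine-grained truth
labels to a coarser vocabulary is a user-supplied mapping, never
hard-coded.

## Evaluation metrics

* **Adjusted Rand index** (Hubert–Arabie): computed from the
  contingency table with exact integer binomial coefficients, so counts
  in the tens of thousands cannot overflow. Identical partitions give
  exactly 1 (the degenerate zero-denominator case is identical trivial
  partitions, defined as 1); independent partitions have expectation 0.
  Tests verify exhaustive agreement with a pair-counting oracle and
  with scikit-learn's implementation.
* **Purity**: `(1/N) Σ_clusters max_class |cluster ∩ class|`, 1 exactly
  when every cluster is class-pure.
* **Intra-type distance**: per class, the mean over all unordered
  within-class pairs of Euclidean distance on the rescaled embedding;
  classes with one cell are reported missing. The overall figure
  averages classes equally by default (small types are not swamped); a
  cell-weighted variant is available. Beyond 10⁶ pairs per class the
  mean is estimated from a seeded random pair subsample.
* **Annotation accuracy**: percentage of cells whose cluster-assigned
  type equals their true type, with per-type recall.

## Synthetic data generator

The generator emulates the features of droplet data the method is
built for, with every parameter explicit in `SimConfig`:

* 5 types × 200 cells over 2,000 genes by default, 20 markers per type
  at 8-fold elevation — a mid-sized, clearly structured experiment.
* Per-gene base rates are log-normal (σ = 2), giving the heavy-tailed
  expression distribution of real data and ~64% zero entries at the
  default depth.
* Marker genes are drawn from the detectable-but-not-ubiquitous band
  of base expression (50th–90th percentile): a near-silent gene is
  never observed even fold-boosted, and a near-ubiquitous one is a
  housekeeping gene whose ICF is ~0 by construction, so neither can
  mark a type.
* Counts are multinomial conditioned on a per-cell depth drawn uniform
  in 2,500–7,500, so depth is exactly controlled and the GF step is
  exercised against known proportions.
* Dropout zeroes each entry with probability
  `logistic(intercept − slope·log1p(expected count))` (intercept −1,
  slope 1): ~25% for barely expressed entries, negligible for high
  expectations — the standard expression-dependent zero-inflation. A
  cell can never lose all its counts (its largest entry is restored if
  dropout empties it).
* Ten mitochondrial genes (`MT-1`…`MT-10`) receive a per-cell UMI
  share drawn uniform in 1–8%, exercising the QC prefix detector below
  its 10% ceiling.

The matched bulk panel gives each type's samples the marker profile at
`marker_fold` with multiplicative log-normal noise (σ = 0.25, 3
samples/type), in the same gene namespace as the counts.

What the generator does **not** emulate: batch effects, continuous
trajectories or doublets, gene–gene correlation beyond type structure,
ambient RNA, and real library-size distributions. Passing the recovery
tests therefore shows the pipeline is correct and self-consistent on
cleanly separated discrete types; it does not certify performance on
real tissues, where type boundaries are fuzzier.

## Problem sizes and determinism

Validation runs use the default 1,000-cell, 2,000-gene configuration
over ten seeds for recovery and for the marker-free negative control;
the acceptance report uses five recovery seeds and three control seeds.
At these sizes a full pass (simulate → annotate) takes a few seconds.
One global seed derives per-stage seeds by CRC-offsetting the stage
name, so any stage can be re-run in isolation with the seed it saw in a
full run; t-SNE runs single-threaded with a fixed seed, and all output
files are written without timestamps, so identical inputs and config
reproduce the artifact tree byte for byte.

## Known limitations

* ICF clamping discards the (weak) information carried by
  everywhere-expressed genes; the literal-formula flag exists but
  produces sign-mixed weight vectors whose inner products are harder to
  interpret.
* Clustering on 2-D t-SNE coordinates inherits t-SNE's local-structure
  distortions; `cluster_space = "meta_genes"` sidesteps this at the
  cost of departing from the published protocol.
* The annotation ranking (fold-change-vs-rest) assumes the panel's
  types are mutually exclusive and reasonably balanced.
* The Jaccard graph is built from exact kNN (chunked O(n²) distance
  evaluation): fine into the tens of thousands of cells, but no
  approximate-neighbor backend is provided.
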