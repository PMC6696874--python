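# gficf

TF-IDF-style normalization, clustering and cell-type annotation for
single-cell RNA-seq UMI count matrices.

Droplet scRNA-seq matrices are extremely sparse and zero-inflated —
exactly the structure of the word-count matrices that text mining has
handled for decades with term frequency–inverse document frequency
(TF-IDF). This package treats each **cell as a document** and each
**gene as a word** and scores gene *i* in cell *j* as

```
GF_ij = f_ij / Σ_k f_kj              (gene frequency: per-cell proportion)
ICF_i = log( N / (n_i + 1) )         (inverse cell frequency; N cells,
                                      n_i cells expressing gene i)
w_ij  = GF_ij · ICF_i,   then each cell column is L2-normalized.
```

GF removes sequencing-depth bias, ICF up-weights genes expressed in a
subpopulation of cells (the informative ones) and zeroes out ubiquitous
housekeeping genes, and the L2 step makes cells directly comparable.
The resulting gf-icf weights feed a standard downstream workflow:

1. top 50 principal components as *meta-genes*;
2. t-SNE (seed 0, perplexity 30) or UMAP into 2-D, coordinates rescaled
   per axis to [−1, 1];
3. a PhenoGraph-style graph — each cell's 50 nearest neighbors under
   Manhattan distance, edges weighted by the Jaccard coefficient of the
   neighbor sets — partitioned with Louvain community detection;
4. per-cluster signatures: the 100 genes with the largest summed gf-icf
   weight, annotated by preranked GSEA against bulk expression profiles
   of purified cell types (highest normalized enrichment score wins);
5. evaluation: adjusted Rand index, cluster purity, per-type intra-type
   embedding distance, per-cell annotation accuracy.

It is aimed at analysts who want a transparent, fully deterministic
alternative to log-normalization pipelines, plus a synthetic-data
generator for validating every stage against planted ground truth.

## Worked example

Generate a synthetic dataset with 3 planted cell types and run the full
pipeline against its matched bulk reference panel:

```bash
gficf simulate --out sim --seed 3 --n-types 3 --cells-per-type 100 --n-genes 800
gficf run --counts sim --out run \
    --truth sim/truth_labels.tsv \
    --panel sim/panel.tsv --panel-labels sim/panel_labels.tsv \
    --perplexity 20 --k-neighbors 30 --min-genes 100 --min-umi 500
```

`run/metrics.json` then contains (values printed by the run above):

```json
{
  "accuracy_pct": 100.0,
  "ari": 0.8694496649391575,
  "intra_type_distance_mean": 0.1715201750304175,
  "modularity": 0.6718431450311609,
  "n_cells": 300,
  "n_clusters": 4,
  "purity": 1.0
}
```

Louvain found 4 communities for the 3 planted types (one type split in
two), so the ARI is 0.87 rather than 1; purity 1.0 means every cluster
is composed of a single true type, and because both sub-clusters were
annotated with the same (correct) type by GSEA, per-cell annotation
accuracy is still 100%. `run/annotation.tsv` holds the per-cluster
enrichment ranking, e.g. cluster 0 is called `type0` with NES 2.50 and
permutation p ≈ 0.003. Other artifacts: `qc_report.tsv` (per-cell QC
statistics and pass/fail), `gficf.mtx` (+ sidecars), `pca.tsv`,
`embedding.tsv`, `graph.tsv`, `clusters.tsv`, `signatures.gmt`.

The same steps are available as library functions
(`gficf.gficf_transform`, `gficf.pca_meta_genes`, `gficf.embed`,
`gficf.knn_graph`, `gficf.louvain_cluster`, `gficf.cluster_signature`,
`gficf.annotate_clusters`, `gficf.run_pipeline`, ...).

Defaults follow the published protocol: QC keeps cells with ≥ 500
detected genes, ≥ 1,500 UMIs and ≤ 10% mitochondrial UMIs; 50 principal
components; t-SNE seed 0, perplexity 30; k = 50 neighbors; top-100
signatures. Identical inputs, config and seeds reproduce output files
byte for byte.

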