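# coexmod

Co-expression gene module detection for single-cell RNA-seq and spatial
transcriptomics count matrices.

Standard single-cell pipelines analyse genes one at a time after clustering
cells, which struggles with rare populations and double-dips into the same
data for clustering and marker calling. `coexmod` inverts the view: it looks
for **modules of co-expressed genes** directly, in cell space, without any
prior cell clustering. The modules — shared or restricted to cell
populations — can then be scored per cell to reveal populations, including
very rare ones.

## Method

Given a gene × cell matrix (log-normalized counts), the pipeline runs four
steps:

1. **Density-based gene selection (DKNN).** A gene–gene distance matrix is
   computed (default: Pearson, *d* = 1 − *r*). Each gene is scored by its
   distance to its *K*-th nearest neighbor gene (DKNN); genes inside a dense
   co-expression neighborhood have small DKNN. A null DKNN distribution is
   simulated by resampling the distance matrix without replacement
   (*n* − 1 draws per simulated gene, *K*-th smallest recorded), an
   empirical false discovery rate
   FDR(*t*) = (#sim ≤ *t*) / *n*<sub>sim</sub> · *n* / #obs ≤ *t*
   is scanned over the observed values, and genes with DKNN at or below the
   largest threshold with FDR ≤ α are kept.
2. **Neighborhood graph.** Either `closest_neighborhood` (edge when B is in
   A's *S* nearest neighbors, *S* < *K*, union-symmetrized) or
   `reciprocal_neighborhood` (mutual-*K*-nearest-neighbor) on the selected
   genes.
3. **Markov clustering (MCL).** The graph's column-stochastic flow matrix is
   alternately expanded (matrix power) and inflated (entrywise power *r* +
   renormalization) until stable; clusters are read off attractor supports.
   Larger inflation *r* gives more, smaller modules.
4. **Module filters and scores.** Filters on module size, supporting cells
   (cells expressing ≥ a fraction of the module) and expression standard
   deviation; per-module top co-expressed genes; and a rank-based per-cell
   module activity score (AUC of the module's recovery curve in each cell's
   top-expressed genes).

A Gamma–Poisson simulator with planted DE gene modules plus AUROC / F1 /
Jaccard metrics reproduce the method's synthetic benchmark design
(7204 genes, 1755 cells, five clusters, DE modules of 500/300/200/50 genes,
fold changes uniform between 4 and 10–100).

## Worked example

`examples/simulate_and_detect.py` simulates an 800-gene × 600-cell dataset
with two planted modules (60 and 40 genes) and runs the full pipeline:

```
dataset: 800 genes x 600 cells, 100 planted DE genes in 2 modules
selection: 163 of 793 genes kept (DKNN threshold 0.670, FDR at threshold 0)
modules: 3 after filtering, sizes [80, 52, 31]
median top Jaccard vs planted modules: 0.821
```

163 genes sit in dense co-expression neighborhoods (DKNN ≤ 0.670, i.e.
their 20th-nearest correlation is ≥ 0.33); after graph clustering and
filtering, three modules remain, and the best-matching predicted module
overlaps each planted one with a median Jaccard of 0.82 (1.0 would be exact
recovery). The other examples print module activity per cell
(`module_activity_scores.py`) and compare the DKNN ranking against a
variance baseline on a small simulation grid (`gene_ranking_benchmark.py`),
e.g. DKNN AUROC 0.99 vs variance AUROC 0.75 at fc_max = 20.

The same pipeline is available from the shell:

```sh
coexmod run --simulate --seed 1 --outdir out/        # self-contained demo
coexmod run --input path/to/10x_dir --outdir out/ \
    --k 50 --fdr 1e-4 --method closest --s 5 --inflation 1.2
coexmod simulate --outdir sim/ --seed 2              # dataset + ground truth
coexmod benchmark --outfile bench.tsv --n-genes 700 --n-cells 500
```

`run` writes the selected-gene table, module GMT/TSV, per-cell module
scores, and a JSON run report whose parameter section fully reproduces the
analysis. `examples/replicate_pbmc3k.py` applies the published settings for
the public PBMC3k dataset (external download required; not part of the test
suite).

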