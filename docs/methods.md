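# Methods

## Overview

`coexmod` detects modules of co-expressed genes in gene × cell (or gene ×
spot) count matrices without prior cell clustering. The pipeline is:
log-normalization → density-based gene selection (DKNN + simulated null +
FDR threshold) → gene neighborhood graph → Markov clustering → module
filters and per-cell activity scores. A Gamma–Poisson simulator with
planted differentially expressed (DE) gene modules provides ground truth
for benchmarking.

## Normalization

`lognormalize` maps counts to `ln(1 + count · sf / cell_total)` with scale
factor `sf = 10 000` by default. Zero-total cells are rejected with an
error listing them; the zero pattern is preserved exactly. Distances are
computed on the log-normalized layer by default — the raw layer can be
passed instead, but correlation distances on raw counts are dominated by
library-size variation.

## Gene–gene distances

Metrics: Pearson (default), Spearman (average-rank ties), cosine, and
unscaled Euclidean. Correlations map to distances as *d* = 1 − *r*
(range [0, 2]): monotone, standard, and anti-correlated genes end up
maximally distant. The full dense matrix is materialized; at the benchmark
scale (7204 genes) this is ~52 M doubles and a few seconds of BLAS time.
Zero-variance genes are an error for correlation metrics; `select_genes`
pre-drops them (and records them) rather than failing mid-pipeline, since
a constant gene carries no co-expression signal by definition.

## DKNN selection

DKNN(*g*) is the distance from gene *g* to its *K*-th nearest neighbor
gene — the *K*-th smallest off-diagonal entry of row *g*, ties sharing rank
by sort order. Defaults: *K* = 50 (closest-neighborhood workflows; ~100 is
recommended for reciprocal graphs), minimum detection `row_sum = 4` cells.

The null distribution is built by resampling the distance matrix without
replacement: the pool is every off-diagonal entry of the rows of "noisy"
genes (observed DKNN at or above the `noise_level` quantile of observed
DKNN; `noise_level = 0` pools every gene, values near 1 pool only the
highest-DKNN genes; default 0.05); each of `n_simulations` iterations draws
*n* − 1 pool values without replacement — one synthetic distance row — and
records its *K*-th smallest. `n_simulations` defaults to the number of
analysed genes. All draws come from one seeded `numpy` generator, so
results are bit-reproducible.

The FDR at a candidate threshold *t* (candidates are the observed values)
is `(mean(sim ≤ t) · n_genes) / max(1, #obs ≤ t)`, capped at 1; the
selection threshold is the largest candidate with FDR ≤ α (default
α = 1e-4) and genes with observed DKNN **at or below** it are selected.
The inclusive comparison keeps the boundary gene, consistent with counting
`#obs ≤ t` as discoveries in the FDR itself. Lowering α can only shrink
the selected set.

## Graph construction and MCL

Neighborhoods for graph building are recomputed among the selected genes
only, with the selection metric. `closest_neighborhood` links each gene to
its *S* nearest selected genes (*S* < *K*; default *S* = 5) and
symmetrizes by union; `reciprocal_neighborhood` requires mutual membership
in *K*-neighborhoods, which prunes harder and favors a larger *K*. Edges
are unweighted; ties in neighbor order are broken by gene order (stable
argsort), making graphs deterministic.

MCL runs on the column-stochastic adjacency (self-loops of weight 1):
expansion = matrix power (default exponent 2), inflation = entrywise power
*r* followed by column renormalization, then pruning of entries below
1e-5 with renormalization. Iteration stops when the largest entry change
drops below 1e-6 (cap 100 iterations; non-convergence is recorded as a
provenance warning and the current flow is interpreted). Clusters are the
supports of attractor rows (positive diagonal); overlapping attractor
systems are merged, and unattached nodes become singletons. The worst
column-sum deviation after each normalization is recorded in provenance
(`mcl_max_colsum_dev`) as a numerical self-check. Inflation defaults to
1.2 (benchmark setting); published analyses of real datasets use 1.8–2.2
for finer modules.

Module ids `M01, M02, ...` are assigned by decreasing module size with ties
broken by the lexicographically smallest member gene, so labels are a pure
function of content.

## Module filters and scores

* `filter_cluster_size`: keep modules with ≥ `min_size` genes (benchmark
  default 10).
* `filter_nb_supporting_cells`: a cell supports a module when it expresses
  (> 0) at least `min_frac` of the module's genes; keep modules with
  ≥ `min_cells` supporting cells (benchmark defaults 5 cells at 20%,
  inclusive). The comparison can be made strict (`>`); both conventions
  appear in published workflows.
* `filter_module_sd`: the statistic is the mean over module genes of the
  per-gene standard deviation across cells (ddof = 1). "Module standard
  deviation" admits several readings (per-gene minimum, pooled expression);
  the mean of per-gene sds was chosen as the least outlier-sensitive and is
  isolated in one function.
* `top_genes`: genes ranked within each module by mean Pearson correlation
  to the other module genes (ties by gene id; undefined correlations score
  0).
* `module_activity_scores`: per cell, genes are ranked by descending
  expression (ties by gene id) and a module scores the area under the
  recovery curve of its genes within the top `ceil(top_fraction · n_genes)`
  ranks, normalized by the best attainable area; `top_fraction` defaults to
  0.05, the conventional window of AUC-style gene-set activity scores. The
  semantics follow those tools; values are not bit-compatible with any of
  them.

All filters are idempotent and commute (each decision depends only on the
module and the matrix).

## Synthetic data

The generator emulates the droplet-style benchmark design: 7204 genes,
1755 cells in five equal clusters, four DE modules of 500/300/200/50 genes,
per-gene fold change uniform on [4, fc_max] with fc_max in 10–100 (grid of
10 × 10 replicates). Counts are Gamma–Poisson:

* relative gene abundances are log-normal (location 0, scale 2 in ln
  units), floored at the abundance yielding one expected count across a
  155-cell reference population — abundance laws are notionally estimated
  from a reference population, and genes undetectable there cannot be
  parameterized;
* each DE module is up-regulated in exactly one target cluster
  (round-robin assignment, recorded in the truth object);
* cluster profiles are renormalized so every cluster's expected library
  matches the drawn one — up-regulation therefore displaces other
  transcripts, the compositional behavior of real sequencing;
* library sizes are log-normal (location 8.0 ≈ 3000 UMIs, scale 0.35), and
  every rate is perturbed by a mean-1 Gamma multiplier (shape 2) before
  Poisson sampling.

These noise defaults give ~89% zeros and droplet-like overdispersion at the
default scale. One seeded stream drives all draws, so a design is
bit-reproducible; grid seeds derive from `SeedSequence((seed, fc_index,
replicate))`.

What the generator does **not** emulate: estimation of abundance laws from
a specific real dataset, batch effects, doublets, cell-cycle structure,
spatial coordinates, and gene–gene correlation *within* the noise genes
beyond what detection and composition induce. Benchmarks on it therefore
show that the pipeline recovers block-structured co-expression under
realistic sparsity — not that it handles those real-data complications.

## Benchmark metrics

AUROC is the Mann–Whitney statistic (ties count ½) of a per-gene score
against the DE truth; for DKNN the score passed in is the negated DKNN.
F1 = 2TP / (2TP + FP + FN) of the selected set, with 0/0 defined as 0.
Module recovery is the pairwise Jaccard matrix between planted and
predicted modules; for each planted module the best Jaccard is taken and
the median of those maxima (midpoint convention) reported. The evaluation
universe is the set of genes surviving the detection pre-filter, and the
truth is intersected with it.

## Numerical and design notes

* Distance matrices are symmetrized as (D + Dᵀ)/2, clipped to their valid
  range, with an exactly zero diagonal; symmetry is enforced to 1e-10.
* Duplicate feature names from 10x input are suffixed `.1`, `.2`, ...,
  escalating on collision.
* Matrices are stored sparsely below 50% density; all operations depend
  only on the values contract, not the representation.
* The CLI run report contains every parameter (including seeds) and no
  timestamps, so identical configurations produce byte-identical artifacts.

## Known limitations

* **FDR behavior on sparsely detected genes.** The null resamples pooled
  distances, which models every gene's distance row as exchangeable draws
  from one pool. On sparse droplet-like data this does not hold: genes
  detected in few cells have high-variance correlation estimates with heavy
  upper tails, so their DKNN values form a heavy left tail the pooled null
  cannot represent, and the FDR step over-selects such genes (a fifth of
  genes on a no-signal dataset at α = 1e-3 under the default design —
  stratified checks show the excess lies almost entirely in genes detected
  in fewer than ~5% of cells). Additionally, with `n_simulations` equal to
  the number of genes, the largest-threshold scan rides the sampling noise
  of the null's extreme order statistics. In practice the downstream module
  filters (size, supporting cells) remove the resulting spurious modules;
  for stricter selection-level control, raise `row_sum` to a few percent of
  cells and increase `n_simulations`.
* DKNN ranking quality (AUROC) is unaffected by the above: it does not
  depend on the threshold.
* MCL granularity depends on inflation; there is no universal best value
  across datasets (1.2 for the coarse benchmark modules, ~2 for fine
  structure). Alternative partitioners (Louvain, Walktrap) are out of
  scope; the graph container is the extension point.
* The exact null-simulation internals of the original R implementation of
  this algorithm family are not published in detail; the resampling scheme
  here is a documented concrete choice, so gene lists on real data are
  expected to be similar but not bit-identical to that package.
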