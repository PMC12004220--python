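"""Optional: run the pipeline on the public PBMC3k dataset.

This script is NOT part of the test suite and needs an external download:
the "pbmc3k_filtered_gene_bc_matrices" archive from the 10x Genomics
website (filtered_gene_bc_matrices/hg19/ contains matrix.mtx, genes.tsv,
barcodes.tsv). Pass that directory as the first argument.

Settings follow the published analysis of this dataset with the original R
implementation of the algorithm: Pearson distances, noise_level 0.05,
FDR 1e-8, closest-neighborhood graph with S = 3, MCL inflation 1.8,
modules kept when they have >= 6 genes and >= 2 cells expressing > 60% of
the module. Results will not be bit-identical to the R package (different
null-simulation internals), so nothing is asserted here.
"""

import sys
from pathlib import Path

import coexmod as cm


def main(tenx_dir: str) -> None:
    matrix = cm.read_10x_mtx(Path(tenx_dir))
    print(f"loaded {matrix.n_genes} genes x {matrix.n_cells} cells")

    # basic quality filtering comparable to the standard workflow
    keep = [g for g, n in zip(matrix.gene_ids, matrix.expressed_cells_per_gene()) if n >= 3]
    matrix = matrix.subset_genes(keep)
    norm = cm.lognormalize(matrix, scale_factor=10_000)

    sel = cm.select_genes(
        norm,
        cm.SelectionParams(
            k_neighbors=50, fdr_target=1e-8, noise_level=0.05, row_sum=3, seed=0
        ),
    )
    print(f"selected {len(sel.selected_genes)} informative genes "
          f"(threshold {sel.threshold})")

    modules = cm.partition_genes(
        norm, sel,
        cm.GraphParams(method="closest_neighborhood", s_closest=3, k_neighbors=50),
        cm.MclParams(inflation=1.8),
    )
    print(f"{modules.n_modules} raw co-expression modules")
    modules = cm.filter_cluster_size(modules, 6)
    modules = cm.filter_nb_supporting_cells(modules, norm, min_cells=2,
                                            min_frac=0.6, strict=True)
    print(f"{modules.n_modules} modules after filtering; "
          f"{len(modules.all_genes())} genes total")

    cm.write_modules_gmt(modules, "pbmc3k_modules.gmt")
    top = cm.top_genes(modules, norm, 20)
    for mid in modules.module_ids()[:5]:
        print(mid, ",".join(top[mid][:8]))


if __name__ == "__main__":
    if len(sys.argv) != 2:
        sys.exit("usage: python replicate_pbmc3k.py <path to filtered 10x directory>")
    main(sys.argv[1])
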