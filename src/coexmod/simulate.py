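"""Synthetic single-cell count data with planted co-expression modules.

The generator emulates the structure of the droplet-style benchmark used to
evaluate the method: a fixed number of cells spread over discrete clusters,
a set of differentially expressed (DE) gene modules — each up-regulated in
one target cluster by a per-gene fold change drawn uniformly from
``[fc_low, fc_max]`` — and realistic count noise. Counts follow a
Gamma-Poisson (negative-binomial-like) law: per-gene relative abundances are
log-normal, per-cell library sizes are log-normal, and each entry's rate is
perturbed by a mean-1 Gamma multiplier before Poisson sampling, giving the
overdispersion and ~90% sparsity typical of droplet data.

Defaults mirror the benchmark design: 7204 genes, 1755 cells, five
clusters, DE modules of 500/300/200/50 genes, fold changes between 4 and a
maximum in 10-100.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .errors import ParameterError
from .matrix import RAW_COUNTS, ExpressionMatrix

_SEED_MOD = 2**31


@dataclass(frozen=True)
class SimulationDesign:
    """Parameters of one synthetic dataset.

    Attributes
    ----------
    n_genes, n_cells, n_clusters
        Matrix dimensions and number of cell clusters.
    cluster_proportions
        Cluster size fractions summing to 1; ``None`` means uniform.
    de_module_sizes
        Sizes of the planted DE gene modules (disjoint gene sets).
    fc_low, fc_max
        Bounds of the uniform fold-change law applied to DE genes in their
        target cluster (``fc_max == fc_low`` degenerates to a constant).
    baseline_mean_log_params
        (location, scale) of the log-normal law for relative gene
        abundances (unitless weights, normalized within cluster).
    dispersion
        Shape of the mean-1 Gamma rate multiplier; smaller values give more
        overdispersion (variance multiplier 1 + 1/shape).
    libsize_log_params
        (location, scale) of the log-normal per-cell library size law, in
        ln(total UMI); the default location 8.0 gives ~3000 UMIs per cell.
    reference_cells
        Size of the notional reference population the abundance law is
        estimated from. Genes undetectable in such a population cannot be
        parameterized, so relative abundances are floored at the level
        yielding one expected count across ``reference_cells`` cells
        (default 155). Set to 0 to disable the floor.
    seed
        Seed of the single random stream used for all draws.
    """

    n_genes: int = 7204
    n_cells: int = 1755
    n_clusters: int = 5
    cluster_proportions: tuple[float, ...] | None = None
    de_module_sizes: tuple[int, ...] = (500, 300, 200, 50)
    fc_low: float = 4.0
    fc_max: float = 100.0
    baseline_mean_log_params: tuple[float, float] = (0.0, 2.0)
    dispersion: float = 2.0
    libsize_log_params: tuple[float, float] = (8.0, 0.35)
    reference_cells: int = 155
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.n_cells < 1 or self.n_clusters < 1:
            raise ParameterError("n_genes, n_cells and n_clusters must be >= 1")
        sizes = tuple(int(s) for s in self.de_module_sizes)
        object.__setattr__(self, "de_module_sizes", sizes)
        if any(s < 1 for s in sizes):
            raise ParameterError("DE module sizes must be positive")
        if sum(sizes) > self.n_genes:
            raise ParameterError("sum of DE module sizes exceeds n_genes")
        if not self.fc_low >= 1:
            raise ParameterError("fc_low must be >= 1")
        if self.fc_max < self.fc_low:
            raise ParameterError("fc_max must be >= fc_low")
        if self.cluster_proportions is not None:
            props = tuple(float(p) for p in self.cluster_proportions)
            object.__setattr__(self, "cluster_proportions", props)
            if len(props) != self.n_clusters:
                raise ParameterError("cluster_proportions length must equal n_clusters")
            if any(p <= 0 for p in props) or abs(sum(props) - 1.0) > 1e-8:
                raise ParameterError("cluster_proportions must be positive and sum to 1")
        if self.dispersion <= 0:
            raise ParameterError("dispersion (Gamma shape) must be positive")
        if self.reference_cells < 0:
            raise ParameterError("reference_cells must be >= 0")

    def proportions(self) -> np.ndarray:
        if self.cluster_proportions is None:
            return np.full(self.n_clusters, 1.0 / self.n_clusters)
        return np.asarray(self.cluster_proportions)


@dataclass
class SyntheticTruth:
    """Ground truth accompanying a simulated dataset."""

    cell_cluster: np.ndarray  # cluster label per cell (ints 0..n_clusters-1)
    de_gene_module: dict[str, int]  # DE gene -> module index (1-based)
    de_fold_change: dict[str, float]
    de_target_cluster: dict[int, int]  # module index -> target cluster label

    @property
    def de_genes(self) -> list[str]:
        return list(self.de_gene_module)

    @property
    def n_modules(self) -> int:
        return len(self.de_target_cluster)

    def module_gene_sets(self) -> list[set[str]]:
        """DE genes grouped by module, ordered by module index."""
        out: dict[int, set[str]] = {m: set() for m in self.de_target_cluster}
        for gene, module in self.de_gene_module.items():
            out[module].add(gene)
        return [out[m] for m in sorted(out)]

    def genes_frame(self) -> pd.DataFrame:
        rows = [
            (g, m, self.de_fold_change[g], self.de_target_cluster[m])
            for g, m in self.de_gene_module.items()
        ]
        return pd.DataFrame(
            rows, columns=["gene", "module_index", "fold_change", "target_cluster"]
        )

    def cells_frame(self, cell_ids: Sequence[str]) -> pd.DataFrame:
        return pd.DataFrame({"cell": list(cell_ids), "cluster": self.cell_cluster})


def _cluster_counts(design: SimulationDesign) -> np.ndarray:
    """Deterministic largest-remainder apportionment of cells to clusters."""
    props = design.proportions()
    raw = props * design.n_cells
    counts = np.floor(raw).astype(int)
    short = design.n_cells - counts.sum()
    order = np.argsort(-(raw - counts), kind="stable")
    counts[order[:short]] += 1
    return counts


def simulate_dataset(design: SimulationDesign) -> tuple[ExpressionMatrix, SyntheticTruth]:
    """Generate one Gamma-Poisson count matrix plus its ground truth.

    All draws come from a single ``numpy.random.default_rng(design.seed)``
    stream, so the same design yields a byte-identical dataset.
    """
    rng = np.random.default_rng(design.seed)
    n_g, n_c, n_k = design.n_genes, design.n_cells, design.n_clusters

    gene_ids = [f"gene_{i + 1:05d}" for i in range(n_g)]
    cell_ids = [f"cell_{i + 1:05d}" for i in range(n_c)]

    loc, scale = design.baseline_mean_log_params
    weights = rng.lognormal(loc, scale, size=n_g)
    if design.reference_cells > 0:
        # abundances are notionally estimated from a reference population:
        # floor at one expected count across reference_cells cells
        lib_loc_, lib_scale_ = design.libsize_log_params
        mean_lib = float(np.exp(lib_loc_ + lib_scale_**2 / 2))
        w_floor = weights.sum() / (design.reference_cells * mean_lib)
        weights = np.maximum(weights, w_floor)

    counts_per_cluster = _cluster_counts(design)
    cell_cluster = np.repeat(np.arange(n_k), counts_per_cluster)

    # plant DE modules: disjoint random gene sets, round-robin target clusters
    n_de = sum(design.de_module_sizes)
    de_idx = rng.choice(n_g, size=n_de, replace=False) if n_de else np.array([], int)
    fold_changes = rng.uniform(design.fc_low, design.fc_max, size=n_de)
    de_gene_module: dict[str, int] = {}
    de_fold_change: dict[str, float] = {}
    de_target_cluster: dict[int, int] = {}
    cluster_weights = np.tile(weights[:, None], (1, n_k))
    start = 0
    for module, size in enumerate(design.de_module_sizes, start=1):
        target = (module - 1) % n_k
        de_target_cluster[module] = target
        for j in range(start, start + size):
            g = int(de_idx[j])
            cluster_weights[g, target] *= fold_changes[j]
            de_gene_module[gene_ids[g]] = module
            de_fold_change[gene_ids[g]] = float(fold_changes[j])
        start += size

    profiles = cluster_weights / cluster_weights.sum(axis=0, keepdims=True)
    lib_loc, lib_scale = design.libsize_log_params
    libsizes = rng.lognormal(lib_loc, lib_scale, size=n_c)

    # per-entry rate: cluster profile * library size * mean-1 Gamma multiplier
    lam = profiles[:, cell_cluster] * libsizes[None, :]
    shape = design.dispersion
    lam *= rng.gamma(shape, 1.0 / shape, size=lam.shape)
    counts = rng.poisson(lam).astype(np.float64)

    matrix = ExpressionMatrix(gene_ids, cell_ids, counts, RAW_COUNTS)
    truth = SyntheticTruth(cell_cluster, de_gene_module, de_fold_change, de_target_cluster)
    return matrix, truth


@dataclass(frozen=True)
class GridCell:
    """One (fc_max, replicate) cell of a simulation grid."""

    fc_max: float
    replicate: int
    design: SimulationDesign

    def simulate(self) -> tuple[ExpressionMatrix, SyntheticTruth]:
        return simulate_dataset(self.design)


def derive_seed(base_seed: int, fc_index: int, replicate: int) -> int:
    """Deterministic per-cell seed below 2**31."""
    ss = np.random.SeedSequence((int(base_seed), int(fc_index), int(replicate)))
    return int(ss.generate_state(1)[0] % _SEED_MOD)


def simulate_grid(
    base: SimulationDesign, fc_max_values: Sequence[float], replicates: int
) -> list[GridCell]:
    """Lazy grid of designs, one per (fc_max, replicate) pair.

    Seeds are derived deterministically from ``(base.seed, fc_max index,
    replicate)``; a collision between two cells raises (never observed for
    practical grids, but checked for honesty).
    """
    if replicates < 1:
        raise ParameterError("replicates must be >= 1")
    if not fc_max_values:
        raise ParameterError("fc_max_values must be non-empty")
    cells: list[GridCell] = []
    seeds: set[int] = set()
    for fi, fc_max in enumerate(fc_max_values):
        for rep in range(replicates):
            seed = derive_seed(base.seed, fi, rep)
            if seed in seeds:
                raise ParameterError(
                    f"derived seed collision at fc_max={fc_max}, replicate={rep}"
                )
            seeds.add(seed)
            design = replace(base, fc_max=float(fc_max), seed=seed)
            cells.append(GridCell(float(fc_max), rep, design))
    return cells
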