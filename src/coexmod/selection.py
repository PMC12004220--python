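"""Density-based informative-gene selection (step i of the algorithm).

Every gene is scored by its distance to the Kth nearest neighbor gene
(DKNN): genes sitting in a dense co-expression neighborhood have a small
DKNN. The observed DKNN distribution is compared with a simulated null
built by resampling the distance matrix without replacement, an empirical
false discovery rate is computed along the sorted observed values, and the
largest DKNN threshold with FDR <= alpha defines the selected gene set.

The null scheme is: pool the off-diagonal distances of the rows of
"noisy" genes (observed DKNN at or above the ``noise_level`` quantile;
``noise_level=0`` pools every gene), then for each simulation draw
``n_genes - 1`` pool values without replacement — one synthetic distance
row — and record its Kth smallest value.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .distance import DistanceMatrix, METRICS, _CORRELATION_METRICS, gene_distance_matrix
from .errors import ParameterError
from .matrix import ExpressionMatrix


@dataclass(frozen=True)
class SelectionParams:
    """Parameters of the DKNN selection step.

    Attributes
    ----------
    k_neighbors
        Neighborhood size K; the DKNN of a gene is its distance to the Kth
        nearest other gene. Default 50 (use ~100 for the reciprocal graph).
    fdr_target
        Acceptable false discovery rate alpha in (0, 1). Default 1e-4.
    noise_level
        Fraction in [0, 1) of low-density (high-DKNN) genes whose distance
        rows feed the null resampling pool; 0 pools all genes. Default 0.05.
    n_simulations
        Null sample size (>= 100). ``None`` means one simulation per
        analysed gene.
    seed
        Seed for the null resampling stream.
    row_sum
        Minimum number of cells a gene must be expressed in (> 0) to enter
        the analysis. Default 4.
    metric
        Distance metric passed to :func:`coexmod.distance.gene_distance_matrix`.
    """

    k_neighbors: int = 50
    fdr_target: float = 1e-4
    noise_level: float = 0.05
    n_simulations: int | None = None
    seed: int = 0
    row_sum: int = 4
    metric: str = "pearson"

    def __post_init__(self) -> None:
        if self.k_neighbors < 1:
            raise ParameterError("k_neighbors must be >= 1")
        if not 0.0 < self.fdr_target < 1.0:
            raise ParameterError("fdr_target must lie in (0, 1)")
        if not 0.0 <= self.noise_level < 1.0:
            raise ParameterError("noise_level must lie in [0, 1)")
        if self.n_simulations is not None and self.n_simulations < 100:
            raise ParameterError("n_simulations must be >= 100")
        if self.row_sum < 0:
            raise ParameterError("row_sum must be >= 0")
        if self.metric not in METRICS:
            raise ParameterError(f"metric must be one of {METRICS}")

    def to_dict(self) -> dict:
        return {
            "k_neighbors": self.k_neighbors,
            "fdr_target": self.fdr_target,
            "noise_level": self.noise_level,
            "n_simulations": self.n_simulations,
            "seed": self.seed,
            "row_sum": self.row_sum,
            "metric": self.metric,
        }


@dataclass
class DknnResult:
    """Observed/simulated DKNN values, FDR threshold and selected genes."""

    gene_ids: list[str]
    observed_dknn: np.ndarray
    simulated_dknn: np.ndarray
    threshold: float | None
    selected_genes: list[str]
    fdr_at_threshold: float
    params: SelectionParams
    dropped_low_rowsum: list[str] = field(default_factory=list)
    dropped_zero_variance: list[str] = field(default_factory=list)

    @property
    def selected_mask(self) -> np.ndarray:
        sel = set(self.selected_genes)
        return np.array([g in sel for g in self.gene_ids])

    def to_frame(self) -> pd.DataFrame:
        """Per-gene DKNN and selection flag (TSV-ready)."""
        return pd.DataFrame(
            {
                "gene": self.gene_ids,
                "dknn": self.observed_dknn,
                "selected": self.selected_mask,
            }
        )

    def summary(self) -> dict:
        return {
            "n_genes_analysed": len(self.gene_ids),
            "n_selected": len(self.selected_genes),
            "threshold": self.threshold,
            "fdr_at_threshold": self.fdr_at_threshold,
            "n_dropped_low_rowsum": len(self.dropped_low_rowsum),
            "n_dropped_zero_variance": len(self.dropped_zero_variance),
            "params": self.params.to_dict(),
        }

    def summary_json(self) -> str:
        return json.dumps(self.summary(), indent=2, sort_keys=True)


# --------------------------------------------------------------------------
# DKNN
# --------------------------------------------------------------------------


def compute_dknn(d: DistanceMatrix, k_neighbors: int) -> np.ndarray:
    """Distance of each gene to its Kth nearest neighbor gene.

    The Kth smallest off-diagonal entry of each row, ties sharing rank by
    sort order.
    """
    n = d.n_genes
    if not 1 <= k_neighbors <= n - 1:
        raise ParameterError(f"k_neighbors must be in [1, {n - 1}], got {k_neighbors}")
    vals = d.values.copy()
    np.fill_diagonal(vals, np.inf)  # exclude self-distance
    part = np.partition(vals, k_neighbors - 1, axis=1)
    return part[:, k_neighbors - 1]


# --------------------------------------------------------------------------
# Null simulation
# --------------------------------------------------------------------------


def _null_pool(d: DistanceMatrix, observed: np.ndarray, noise_level: float) -> np.ndarray:
    """Off-diagonal distances from rows of genes in the noise pool."""
    cutoff = np.quantile(observed, noise_level)
    pool_rows = np.where(observed >= cutoff)[0]
    n = d.n_genes
    block = d.values[pool_rows]
    mask = np.ones(block.shape, dtype=bool)
    mask[np.arange(len(pool_rows)), pool_rows] = False  # drop self-distances
    return block[mask]


def simulate_null_dknn(
    d: DistanceMatrix, observed: np.ndarray, params: SelectionParams
) -> np.ndarray:
    """Simulate the DKNN null by resampling pooled distances.

    For each of ``n_simulations`` iterations, draw ``n_genes - 1`` distances
    without replacement from the noise pool (a synthetic distance row) and
    record the Kth smallest. Deterministic given ``params.seed``.
    """
    observed = np.asarray(observed, dtype=np.float64)
    if observed.shape != (d.n_genes,):
        raise ParameterError("observed DKNN must align with the distance matrix")
    pool = _null_pool(d, observed, params.noise_level)
    n_draw = d.n_genes - 1
    if pool.size < n_draw:
        raise ParameterError(
            f"noise pool has {pool.size} distances but {n_draw} are drawn per "
            "simulation; lower noise_level"
        )
    n_sim = params.n_simulations or max(100, d.n_genes)
    k = params.k_neighbors
    if k > n_draw:
        raise ParameterError("k_neighbors exceeds the simulated row length")
    rng = np.random.default_rng(params.seed)
    out = np.empty(n_sim)
    for i in range(n_sim):
        idx = rng.choice(pool.size, size=n_draw, replace=False)
        out[i] = np.partition(pool[idx], k - 1)[k - 1]
    return out


# --------------------------------------------------------------------------
# FDR threshold
# --------------------------------------------------------------------------


def estimate_fdr_threshold(
    observed: np.ndarray, simulated: np.ndarray, alpha: float
) -> tuple[float | None, float]:
    """Largest observed-DKNN candidate whose empirical FDR is <= alpha.

    For each candidate t (an observed value),
    ``FDR(t) = (mean(simulated <= t) * n_genes) / max(1, #observed <= t)``,
    capped at 1. Returns ``(None, 1.0)`` when no candidate qualifies.
    """
    observed = np.asarray(observed, dtype=np.float64)
    simulated = np.asarray(simulated, dtype=np.float64)
    if observed.size == 0 or simulated.size == 0:
        raise ParameterError("observed and simulated samples must be non-empty")
    if not 0.0 < alpha < 1.0:
        raise ParameterError("alpha must lie in (0, 1)")
    obs_sorted = np.sort(observed)
    sim_sorted = np.sort(simulated)
    candidates = np.unique(observed)
    n_obs_le = np.searchsorted(obs_sorted, candidates, side="right")
    n_sim_le = np.searchsorted(sim_sorted, candidates, side="right")
    fdr = (n_sim_le / simulated.size * observed.size) / np.maximum(1, n_obs_le)
    fdr = np.minimum(fdr, 1.0)
    ok = np.where(fdr <= alpha)[0]
    if ok.size == 0:
        return None, 1.0
    best = ok[np.argmax(candidates[ok])]
    return float(candidates[best]), float(fdr[best])


# --------------------------------------------------------------------------
# Full selection step
# --------------------------------------------------------------------------


def select_genes(m: ExpressionMatrix, params: SelectionParams | None = None) -> DknnResult:
    """Run the full density-based selection on an expression matrix.

    Composes: row_sum pre-filter -> distance matrix -> observed DKNN ->
    null simulation -> FDR threshold. Genes with zero variance across cells
    (undefined correlation) are dropped alongside the row_sum filter and
    reported in the result. Genes with observed DKNN at or below the
    threshold are selected; with no qualifying threshold the selection is
    empty. Fully deterministic given ``params.seed``.
    """
    params = params or SelectionParams()
    expressed = m.expressed_cells_per_gene()
    keep = expressed >= params.row_sum
    dropped_low = [g for g, k in zip(m.gene_ids, keep) if not k]

    dropped_var: list[str] = []
    if params.metric in _CORRELATION_METRICS or params.metric == "cosine":
        x = m.dense()
        var = x.var(axis=1)
        bad = (var == 0) & keep
        dropped_var = [m.gene_ids[i] for i in np.where(bad)[0]]
        keep &= var > 0

    kept_genes = [g for g, k in zip(m.gene_ids, keep) if k]
    if len(kept_genes) <= params.k_neighbors:
        raise ParameterError(
            f"{len(kept_genes)} genes survive the pre-filter but "
            f"k_neighbors={params.k_neighbors} requires at least "
            f"{params.k_neighbors + 1}"
        )
    sub = m.subset_genes(kept_genes)
    d = gene_distance_matrix(sub, params.metric)
    observed = compute_dknn(d, params.k_neighbors)
    simulated = simulate_null_dknn(d, observed, params)
    threshold, fdr = estimate_fdr_threshold(observed, simulated, params.fdr_target)
    if threshold is None:
        selected: list[str] = []
    else:
        selected = [g for g, v in zip(kept_genes, observed) if v <= threshold]
    return DknnResult(
        gene_ids=kept_genes,
        observed_dknn=observed,
        simulated_dknn=simulated,
        threshold=threshold,
        selected_genes=selected,
        fdr_at_threshold=fdr,
        params=params,
        dropped_low_rowsum=dropped_low,
        dropped_zero_variance=dropped_var,
    )
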