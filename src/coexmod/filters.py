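"""Module filtering, summarization and per-cell activity scoring (step iv).

MCL tends to emit many tiny or weakly supported clusters, so the pipeline
ends with filters on module size, on the number of supporting cells (cells
expressing at least a given fraction of a module's genes) and on expression
standard deviation, plus two summaries: the most highly co-expressed genes
of each module and a rank-based per-cell module activity score.

Every filter is idempotent and decides each module's survival from the
module and the matrix alone, so filters commute.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ParameterError
from .matrix import ExpressionMatrix
from .moduleset import ModuleSet


@dataclass(frozen=True)
class FilterParams:
    """Bundle of the filter thresholds used by the full pipeline.

    ``min_frac`` is compared inclusively by default; ``strict_frac=True``
    switches to a strict ``>`` comparison (both conventions appear in
    published workflows, e.g. "expressed 20%" vs "expressing >60%").
    """

    min_size: int = 10
    min_cells: int = 5
    min_frac: float = 0.2
    strict_frac: bool = False
    min_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.min_size < 1:
            raise ParameterError("min_size must be >= 1")
        if self.min_cells < 0:
            raise ParameterError("min_cells must be >= 0")
        if not 0.0 <= self.min_frac <= 1.0:
            raise ParameterError("min_frac must lie in [0, 1]")
        if not (self.min_sd >= 0 and math.isfinite(self.min_sd)):
            raise ParameterError("min_sd must be a finite non-negative number")

    def to_dict(self) -> dict:
        return {
            "min_size": self.min_size,
            "min_cells": self.min_cells,
            "min_frac": self.min_frac,
            "strict_frac": self.strict_frac,
            "min_sd": self.min_sd,
        }


def _rebuild(ms: ModuleSet, survivors: list[list[str]], note: dict) -> ModuleSet:
    prov = dict(ms.provenance)
    prov.setdefault("filters", [])
    prov["filters"] = list(prov["filters"]) + [note]
    return ModuleSet.from_gene_lists(survivors, prov)


def filter_cluster_size(ms: ModuleSet, min_size: int) -> ModuleSet:
    """Keep modules with at least ``min_size`` genes."""
    if min_size < 1:
        raise ParameterError("min_size must be >= 1")
    survivors = [genes for genes in ms.gene_lists() if len(genes) >= min_size]
    return _rebuild(ms, survivors, {"filter": "cluster_size", "min_size": min_size})


def supporting_cells(
    module_genes: list[str],
    m_expr: ExpressionMatrix,
    min_frac: float,
    strict: bool = False,
) -> int:
    """Number of cells expressing at least (or more than) ``min_frac`` of a module."""
    idx = m_expr.gene_index(module_genes)
    vals = m_expr.values[idx] if hasattr(m_expr.values, "tocsr") else m_expr.values[idx, :]
    expressed = np.asarray((vals > 0).sum(axis=0)).ravel()
    frac = expressed / len(module_genes)
    hit = frac > min_frac if strict else frac >= min_frac
    return int(hit.sum())


def filter_nb_supporting_cells(
    ms: ModuleSet,
    m_expr: ExpressionMatrix,
    min_cells: int,
    min_frac: float,
    strict: bool = False,
) -> ModuleSet:
    """Keep modules supported by at least ``min_cells`` cells.

    A cell supports a module when the fraction of the module's genes it
    expresses (value > 0) is ``>= min_frac`` (or ``>`` when ``strict``).
    """
    if min_cells < 0:
        raise ParameterError("min_cells must be >= 0")
    if not 0.0 <= min_frac <= 1.0:
        raise ParameterError("min_frac must lie in [0, 1]")
    survivors = []
    for mid, genes in ms.modules.items():
        try:
            n_support = supporting_cells(genes, m_expr, min_frac, strict)
        except ParameterError as exc:
            raise ParameterError(f"module {mid}: {exc}") from exc
        if n_support >= min_cells:
            survivors.append(genes)
    return _rebuild(
        ms,
        survivors,
        {
            "filter": "nb_supporting_cells",
            "min_cells": min_cells,
            "min_frac": min_frac,
            "strict": strict,
        },
    )


def module_sd(module_genes: list[str], m_expr: ExpressionMatrix) -> float:
    """Mean over module genes of the per-gene standard deviation (ddof=1)."""
    sub = m_expr.subset_genes(module_genes).dense()
    if sub.shape[1] < 2:
        return 0.0
    return float(sub.std(axis=1, ddof=1).mean())


def filter_module_sd(ms: ModuleSet, m_expr: ExpressionMatrix, min_sd: float) -> ModuleSet:
    """Keep modules whose mean per-gene standard deviation is >= ``min_sd``."""
    if not (min_sd >= 0 and math.isfinite(min_sd)):
        raise ParameterError("min_sd must be a finite non-negative number")
    survivors = []
    for mid, genes in ms.modules.items():
        try:
            sd = module_sd(genes, m_expr)
        except ParameterError as exc:
            raise ParameterError(f"module {mid}: {exc}") from exc
        if sd >= min_sd:
            survivors.append(genes)
    return _rebuild(ms, survivors, {"filter": "module_sd", "min_sd": min_sd})


def top_genes(
    ms: ModuleSet, m_expr: ExpressionMatrix, n_top: int = 20
) -> dict[str, list[str]]:
    """The most highly co-expressed genes of each module.

    Genes are ranked within their module by mean Pearson correlation to the
    other module genes (descending; ties broken by gene id; undefined
    correlations, e.g. for a single-gene or constant-gene module, count
    as 0). Returns the first ``min(n_top, |module|)`` genes per module.
    """
    if n_top < 1:
        raise ParameterError("n_top must be >= 1")
    out: dict[str, list[str]] = {}
    for mid, genes in ms.modules.items():
        if len(genes) == 1:
            out[mid] = list(genes)
            continue
        x = m_expr.subset_genes(genes).dense()
        sd = x.std(axis=1)
        xc = x - x.mean(axis=1, keepdims=True)
        safe = sd.copy()
        safe[safe == 0] = 1.0
        xn = xc / (safe[:, None] * np.sqrt(x.shape[1]))
        corr = xn @ xn.T
        corr[sd == 0, :] = 0.0
        corr[:, sd == 0] = 0.0
        mean_corr = (corr.sum(axis=1) - np.diagonal(corr)) / (len(genes) - 1)
        order = sorted(range(len(genes)), key=lambda i: (-mean_corr[i], genes[i]))
        out[mid] = [genes[i] for i in order[:n_top]]
    return out


def module_activity_scores(
    ms: ModuleSet, m_expr: ExpressionMatrix, top_fraction: float = 0.05
) -> pd.DataFrame:
    """Rank-based per-cell module activity (modules x cells, values in [0, 1]).

    For each cell, all genes are ranked by descending expression (ties by
    gene id), and a module's score is the area under the recovery curve of
    its genes within the top ``ceil(top_fraction * n_genes)`` ranks,
    normalized by the maximum attainable area. A cell whose top-ranked
    genes are exactly the module scores 1; a cell expressing none of the
    module's genes in the window scores 0. Semantics follow the AUC-style
    gene-set activity scores common in single-cell analysis (not
    bit-compatible with any particular implementation).
    """
    if not 0.0 < top_fraction <= 1.0:
        raise ParameterError("top_fraction must lie in (0, 1]")
    x = m_expr.dense()
    n_genes, n_cells = x.shape
    window = int(math.ceil(top_fraction * n_genes))
    tie_rank = np.argsort(np.argsort(np.array(m_expr.gene_ids)))
    # position of each gene in the per-cell descending-expression order
    positions = np.empty((n_genes, n_cells), dtype=np.int64)
    for c in range(n_cells):
        order = np.lexsort((tie_rank, -x[:, c]))
        positions[order, c] = np.arange(n_genes)
    scores = np.zeros((len(ms.modules), n_cells))
    for r, (mid, genes) in enumerate(ms.modules.items()):
        idx = m_expr.gene_index(genes)
        pos = positions[idx, :]
        inside = pos < window
        raw = np.where(inside, window - pos, 0).sum(axis=0)
        k = min(len(genes), window)
        max_area = (window - np.arange(k)).sum()
        scores[r] = raw / max_area
    return pd.DataFrame(scores, index=list(ms.modules), columns=m_expr.cell_ids)
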