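"""Gene-gene dissimilarity matrices.

The density-based gene filtering and the neighborhood graphs both consume a
symmetric gene x gene distance matrix computed across cells. Correlation
metrics use the standard ``d = 1 - r`` map (range [0, 2], anti-correlated
genes maximally distant); cosine is ``1 - cosine similarity``; Euclidean is
the unscaled L2 distance between gene rows. The full dense matrix is
materialized (~52M entries at the 7204-gene scale of a typical run).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform
from scipy.stats import rankdata

from .errors import ParameterError
from .matrix import ExpressionMatrix

METRICS = ("pearson", "spearman", "euclidean", "cosine")
_CORRELATION_METRICS = ("pearson", "spearman")
_BOUNDED_METRICS = ("pearson", "spearman", "cosine")


@dataclass
class DistanceMatrix:
    """Symmetric gene x gene dissimilarities under a named metric."""

    gene_ids: list[str]
    values: np.ndarray
    metric: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        n = len(self.gene_ids)
        if self.values.shape != (n, n):
            raise ParameterError("distance matrix shape must be n_genes x n_genes")
        if self.metric not in METRICS:
            raise ParameterError(f"metric must be one of {METRICS}")
        if not np.all(np.isfinite(self.values)):
            raise ParameterError("distance matrix must be finite")
        if np.abs(self.values - self.values.T).max(initial=0.0) > 1e-10:
            raise ParameterError("distance matrix must be symmetric within 1e-10")
        if n and np.abs(np.diagonal(self.values)).max() != 0.0:
            raise ParameterError("distance matrix diagonal must be exactly 0")
        if self.values.size and self.values.min() < 0:
            raise ParameterError("distances must be non-negative")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def subset(self, genes) -> "DistanceMatrix":
        lookup = {g: i for i, g in enumerate(self.gene_ids)}
        idx = np.array([lookup[g] for g in genes], dtype=int)
        return DistanceMatrix(list(genes), self.values[np.ix_(idx, idx)], self.metric)


def _finalize(d: np.ndarray, gene_ids, metric: str) -> DistanceMatrix:
    d = (d + d.T) / 2.0
    np.clip(d, 0.0, 2.0 if metric in _BOUNDED_METRICS else None, out=d)
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(list(gene_ids), d, metric)


def _correlation_distance(x: np.ndarray) -> np.ndarray:
    mean = x.mean(axis=1, keepdims=True)
    xc = x - mean
    norms = np.sqrt((xc * xc).sum(axis=1))
    xc /= norms[:, None]
    return 1.0 - xc @ xc.T


def gene_distance_matrix(m: ExpressionMatrix, metric: str = "pearson") -> DistanceMatrix:
    """Compute the gene-gene distance matrix across cells.

    Parameters
    ----------
    m
        Expression matrix (genes x cells). Correlation metrics need >= 3
        cells and no zero-variance gene; pre-filter such genes (e.g. via the
        ``row_sum`` option of the selection step) before calling.
    metric
        One of ``pearson``, ``spearman``, ``euclidean``, ``cosine``.
    """
    if metric not in METRICS:
        raise ParameterError(f"metric must be one of {METRICS}, got {metric!r}")
    if m.n_genes < 2:
        raise ParameterError("need at least 2 genes for a distance matrix")
    x = m.dense()
    if metric in _CORRELATION_METRICS:
        if m.n_cells < 3:
            raise ParameterError("correlation metrics need at least 3 cells")
        var = x.var(axis=1)
        if (var == 0).any():
            bad = [m.gene_ids[i] for i in np.where(var == 0)[0][:10]]
            raise ParameterError(
                f"zero-variance genes under metric {metric!r}: {bad} "
                "(pre-filter via row_sum / variance)"
            )
    if metric == "pearson":
        d = _correlation_distance(x)
    elif metric == "spearman":
        d = _correlation_distance(rankdata(x, axis=1))
    elif metric == "cosine":
        norms = np.sqrt((x * x).sum(axis=1))
        if (norms == 0).any():
            bad = [m.gene_ids[i] for i in np.where(norms == 0)[0][:10]]
            raise ParameterError(f"all-zero genes under cosine metric: {bad}")
        xn = x / norms[:, None]
        d = 1.0 - xn @ xn.T
    else:  # euclidean
        d = squareform(pdist(x, metric="euclidean"))
    return _finalize(d, m.gene_ids, metric)
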