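"""The gene x cell expression matrix container.

Genes are rows and cells (or spatial spots) are columns everywhere in this
package: the method analyses genes in cell space, so the gene axis is primary.
Transposed dense input is the caller's responsibility.

Values are held either as a dense :class:`numpy.ndarray` or a
:class:`scipy.sparse.csr_matrix`; every operation relies only on the
contract (finite, non-negative, integer when the layer is raw counts),
never on the concrete representation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import scipy.sparse as sp

from .errors import ParameterError

#: layer tag for unnormalized UMI/read counts
RAW_COUNTS = "raw_counts"
#: layer tag for log-normalized expression (see :func:`coexmod.io.lognormalize`)
LOGNORM = "lognorm"

_LAYERS = (RAW_COUNTS, LOGNORM)

#: store sparsely below this density (representation detail, not contract)
_SPARSE_DENSITY = 0.5


def _as_storage(values, layer: str):
    """Pick dense/sparse storage by density; validate finiteness/sign."""
    if sp.issparse(values):
        values = values.tocsr()
        data = values.data
    else:
        values = np.asarray(values, dtype=np.float64)
        if values.ndim != 2:
            raise ParameterError("expression values must be a 2-D matrix")
        data = values
    if data.size and not np.all(np.isfinite(data)):
        raise ParameterError("expression values must be finite (no NaN/Inf)")
    if data.size and (np.asarray(data) < 0).any():
        raise ParameterError("expression values must be non-negative")
    if layer == RAW_COUNTS and data.size:
        arr = np.asarray(data)
        if not np.array_equal(arr, np.floor(arr)):
            raise ParameterError("raw_counts layer requires integer values")
    # normalize representation: sparse below the density cut-off
    if sp.issparse(values):
        density = values.nnz / max(1, values.shape[0] * values.shape[1])
        if density >= _SPARSE_DENSITY:
            values = values.toarray()
    else:
        density = np.count_nonzero(values) / max(1, values.size)
        if density < _SPARSE_DENSITY and min(values.shape) > 0:
            values = sp.csr_matrix(values)
    return values


def _check_unique(ids: Sequence[str], axis: str) -> list[str]:
    ids = [str(i) for i in ids]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ParameterError(f"duplicate {axis} ids: {dupes[:5]}")
    return ids


@dataclass
class ExpressionMatrix:
    """Gene x cell expression matrix with id vectors and a layer tag.

    Parameters
    ----------
    gene_ids
        Unique gene identifiers, one per row.
    cell_ids
        Unique cell (or spot) identifiers, one per column.
    values
        ``|genes| x |cells|`` matrix, finite and non-negative; integer when
        ``layer == "raw_counts"``.
    layer
        Either ``"raw_counts"`` or ``"lognorm"``.
    """

    gene_ids: list[str]
    cell_ids: list[str]
    values: object
    layer: str = RAW_COUNTS

    def __post_init__(self) -> None:
        if self.layer not in _LAYERS:
            raise ParameterError(f"layer must be one of {_LAYERS}, got {self.layer!r}")
        self.gene_ids = _check_unique(self.gene_ids, "gene")
        self.cell_ids = _check_unique(self.cell_ids, "cell")
        self.values = _as_storage(self.values, self.layer)
        if self.values.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise ParameterError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.cell_ids)} cells"
            )

    # -- basic accessors -------------------------------------------------
    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_genes, self.n_cells)

    def dense(self) -> np.ndarray:
        """Return values as a dense float64 array (copy only if sparse)."""
        if sp.issparse(self.values):
            return np.asarray(self.values.toarray(), dtype=np.float64)
        return np.asarray(self.values, dtype=np.float64)

    def gene_index(self, genes: Sequence[str]) -> np.ndarray:
        lookup = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in genes if g not in lookup]
        if missing:
            raise ParameterError(f"genes absent from matrix: {missing[:5]}")
        return np.array([lookup[g] for g in genes], dtype=int)

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionMatrix":
        """Row-subset to ``genes`` (order preserved as given)."""
        idx = self.gene_index(genes)
        vals = self.values[idx] if sp.issparse(self.values) else self.values[idx, :]
        return ExpressionMatrix(
            [self.gene_ids[i] for i in idx], list(self.cell_ids), vals, self.layer
        )

    def expressed_cells_per_gene(self) -> np.ndarray:
        """Number of cells with value > 0, per gene."""
        if sp.issparse(self.values):
            return np.asarray((self.values > 0).sum(axis=1)).ravel()
        return (self.values > 0).sum(axis=1)

    def cell_totals(self) -> np.ndarray:
        """Per-cell column sums."""
        if sp.issparse(self.values):
            return np.asarray(self.values.sum(axis=0)).ravel()
        return self.values.sum(axis=0)
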