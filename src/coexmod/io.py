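"""Reading/writing expression matrices and gene-module sets.

Supported formats: 10x-style MatrixMarket triplet directories
(``matrix.mtx[.gz]`` + ``features.tsv``/``genes.tsv`` + ``barcodes.tsv``,
optionally gzipped), dense TSV with gene rows and cell columns, the GMT
gene-set format, and a two-column gene/module TSV table. Also provides the
log-normalization applied upstream of distance computation.
"""

from __future__ import annotations

import gzip
import math
import os
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.io import mmread, mmwrite

from .errors import InputFileError, MatrixFormatError, ParameterError
from .matrix import LOGNORM, RAW_COUNTS, ExpressionMatrix
from .moduleset import ModuleSet

# --------------------------------------------------------------------------
# 10x MatrixMarket directories
# --------------------------------------------------------------------------

_FEATURE_CANDIDATES = ("features.tsv", "features.tsv.gz", "genes.tsv", "genes.tsv.gz")
_BARCODE_CANDIDATES = ("barcodes.tsv", "barcodes.tsv.gz")
_MATRIX_CANDIDATES = ("matrix.mtx", "matrix.mtx.gz")


def _find(directory: Path, candidates: Sequence[str], what: str) -> Path:
    for name in candidates:
        p = directory / name
        if p.exists():
            return p
    raise InputFileError(
        f"no {what} file in {directory} (looked for {', '.join(candidates)})"
    )


def _read_tsv_column(path: Path, column: int | None = None) -> list[str]:
    opener = gzip.open if path.suffix == ".gz" else open
    rows: list[list[str]] = []
    with opener(path, "rt") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line:
                rows.append(line.split("\t"))
    if not rows:
        return []
    if column is None:
        # features files carry (id, name[, type]); prefer the name column
        column = 1 if all(len(r) >= 2 for r in rows) else 0
    return [r[column] for r in rows]


def deduplicate_ids(ids: Sequence[str]) -> list[str]:
    """Make ids unique by suffixing ``.1``, ``.2`` ... to repeats.

    If the suffixed name collides with an existing id the suffix index is
    escalated until the name is free, so the result is always unique and
    deterministic.
    """
    taken = set()
    counts: dict[str, int] = {}
    out = []
    for raw in ids:
        name = str(raw)
        if name in taken:
            k = counts.get(name, 0) + 1
            candidate = f"{name}.{k}"
            while candidate in taken or candidate in ids[len(out):]:
                k += 1
                candidate = f"{name}.{k}"
            counts[name] = k
            name = candidate
        counts.setdefault(name, 0)
        taken.add(name)
        out.append(name)
    return out


def read_10x_mtx(directory_path: str | os.PathLike) -> ExpressionMatrix:
    """Read a 10x-style MatrixMarket triplet directory as raw counts.

    Genes are matrix rows, cells columns. Duplicate feature names are
    disambiguated with deterministic numeric suffixes (``A``, ``A.1``, ...).
    """
    directory = Path(directory_path)
    if not directory.is_dir():
        raise InputFileError(f"not a directory: {directory}")
    mtx_path = _find(directory, _MATRIX_CANDIDATES, "matrix.mtx")
    feat_path = _find(directory, _FEATURE_CANDIDATES, "features/genes TSV")
    bc_path = _find(directory, _BARCODE_CANDIDATES, "barcodes TSV")

    opener = gzip.open if mtx_path.suffix == ".gz" else open
    try:
        with opener(mtx_path, "rb") as fh:
            mat = mmread(fh)
    except Exception as exc:  # malformed MatrixMarket header/body
        raise MatrixFormatError(f"cannot parse {mtx_path}: {exc}") from exc

    genes = _read_tsv_column(feat_path)
    cells = _read_tsv_column(bc_path, column=0)
    if mat.shape != (len(genes), len(cells)):
        raise MatrixFormatError(
            f"matrix header declares {mat.shape[0]} x {mat.shape[1]} but "
            f"{feat_path.name} has {len(genes)} rows and "
            f"{bc_path.name} has {len(cells)} rows"
        )
    return ExpressionMatrix(
        deduplicate_ids(genes), deduplicate_ids(cells), sp.csr_matrix(mat), RAW_COUNTS
    )


def write_10x_mtx(m: ExpressionMatrix, directory_path: str | os.PathLike) -> None:
    """Write ``m`` as an uncompressed 10x-style triplet directory."""
    directory = Path(directory_path)
    directory.mkdir(parents=True, exist_ok=True)
    vals = m.values if sp.issparse(m.values) else sp.csr_matrix(m.values)
    field = "integer" if m.layer == RAW_COUNTS else "real"
    coo = vals.tocoo()
    if field == "integer":
        coo = sp.coo_matrix((coo.data.astype(np.int64), (coo.row, coo.col)), coo.shape)
    mmwrite(str(directory / "matrix.mtx"), coo, field=field)
    with open(directory / "features.tsv", "w") as fh:
        for g in m.gene_ids:
            fh.write(f"{g}\t{g}\tGene Expression\n")
    with open(directory / "barcodes.tsv", "w") as fh:
        for c in m.cell_ids:
            fh.write(c + "\n")


# --------------------------------------------------------------------------
# Dense TSV
# --------------------------------------------------------------------------


def read_dense_tsv(file_path: str | os.PathLike, layer: str = RAW_COUNTS) -> ExpressionMatrix:
    """Read a dense TSV (header row = cell ids, first column = gene ids)."""
    path = Path(file_path)
    if not path.exists():
        raise InputFileError(f"no such file: {path}")
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    except pd.errors.ParserError as exc:
        raise MatrixFormatError(f"{path}: {exc}") from exc
    if df.isna().any().any():
        r, c = next(zip(*np.where(df.isna().values)))
        raise MatrixFormatError(
            f"{path}: missing value at row {df.index[r]!r}, column {df.columns[c]!r} "
            "(ragged or incomplete line)"
        )
    try:
        values = df.astype(float).values
    except ValueError:
        for r in range(df.shape[0]):
            for c in range(df.shape[1]):
                try:
                    float(df.iat[r, c])
                except ValueError:
                    raise MatrixFormatError(
                        f"{path}: non-numeric value {df.iat[r, c]!r} at "
                        f"row {df.index[r]!r}, column {df.columns[c]!r}"
                    ) from None
        raise  # pragma: no cover - unreachable
    return ExpressionMatrix(list(df.index), list(df.columns), values, layer)


def write_dense_tsv(m: ExpressionMatrix, file_path: str | os.PathLike) -> None:
    vals = m.dense()
    if m.layer == RAW_COUNTS:
        vals = vals.astype(np.int64)
    df = pd.DataFrame(vals, index=m.gene_ids, columns=m.cell_ids)
    df.to_csv(file_path, sep="\t")


# --------------------------------------------------------------------------
# Normalization
# --------------------------------------------------------------------------


def lognormalize(m: ExpressionMatrix, scale_factor: float = 10_000.0) -> ExpressionMatrix:
    """Library-size log-normalization: ``ln(1 + count * sf / cell_total)``.

    Each cell's counts are scaled to a common total (``scale_factor``,
    default 10 000) and shifted-log transformed, so values are comparable
    across cells of different sequencing depth. The zero pattern of the
    raw matrix is preserved exactly.
    """
    if m.layer != RAW_COUNTS:
        raise ParameterError("lognormalize expects a raw_counts matrix")
    if not (scale_factor > 0 and math.isfinite(scale_factor)):
        raise ParameterError("scale_factor must be a positive finite number")
    totals = m.cell_totals()
    zero = totals <= 0
    if zero.any():
        bad = [m.cell_ids[i] for i in np.where(zero)[0][:10]]
        raise ParameterError(f"cells with zero total count: {bad}")
    if sp.issparse(m.values):
        out = m.values.tocsc(copy=True).astype(np.float64)
        out.data *= scale_factor / np.repeat(totals, np.diff(out.indptr))
        out.data = np.log1p(out.data)
        out = out.tocsr()
    else:
        out = np.log1p(m.dense() * (scale_factor / totals))
    return ExpressionMatrix(list(m.gene_ids), list(m.cell_ids), out, LOGNORM)


# --------------------------------------------------------------------------
# Module sets: GMT and TSV
# --------------------------------------------------------------------------


def write_modules_gmt(
    ms: ModuleSet, file_path: str | os.PathLike, description: str = "coexmod module"
) -> None:
    """Write one GMT line per module: ``id TAB description TAB gene...``."""
    try:
        with open(file_path, "w") as fh:
            for mid, genes in ms.modules.items():
                fh.write("\t".join([mid, description, *genes]) + "\n")
    except OSError as exc:
        raise InputFileError(f"cannot write {file_path}: {exc}") from exc


def read_modules_gmt(file_path: str | os.PathLike) -> ModuleSet:
    path = Path(file_path)
    if not path.exists():
        raise InputFileError(f"no such file: {path}")
    modules: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise MatrixFormatError(
                    f"{path}:{lineno}: GMT lines need id, description and >=1 gene"
                )
            modules[parts[0]] = parts[2:]
    return ModuleSet(modules)


def write_modules_tsv(ms: ModuleSet, file_path: str | os.PathLike) -> None:
    """Two-column table (gene, module_id), one row per gene."""
    rows = [(g, mid) for mid, genes in ms.modules.items() for g in genes]
    pd.DataFrame(rows, columns=["gene", "module_id"]).to_csv(
        file_path, sep="\t", index=False
    )


def read_modules_tsv(file_path: str | os.PathLike) -> ModuleSet:
    path = Path(file_path)
    if not path.exists():
        raise InputFileError(f"no such file: {path}")
    df = pd.read_csv(path, sep="\t", dtype=str)
    if list(df.columns) != ["gene", "module_id"]:
        raise MatrixFormatError(f"{path}: expected columns gene, module_id")
    modules: dict[str, list[str]] = {}
    for gene, mid in df.itertuples(index=False):
        modules.setdefault(mid, []).append(gene)
    return ModuleSet(modules)
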