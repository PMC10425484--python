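"""Expression-matrix containers and plain-text I/O.

The package works on genes x cells integer count matrices carried as
:class:`ExpressionMatrix`, together with a per-cell metadata table
(condition, developmental stage, embryo of origin) and optional gene
lengths in base pairs (needed for TPM on full-length protocols).
Matrices round-trip through MatrixMarket (MTX) or plain TSV.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

logger = logging.getLogger(__name__)

REQUIRED_META_COLUMNS = ("condition", "stage", "embryo_id")


@dataclass
class ExpressionMatrix:
    """Integer gene x cell count matrix with cell metadata.

    Parameters
    ----------
    counts
        genes x cells DataFrame of nonnegative integers; index = gene ids,
        columns = cell ids.
    cell_meta
        DataFrame indexed by cell id with at least ``condition``, ``stage``
        and ``embryo_id`` columns.
    gene_lengths
        Optional Series of positive gene lengths (bp), indexed like
        ``counts``.
    """

    counts: pd.DataFrame
    cell_meta: pd.DataFrame
    gene_lengths: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.counts.columns.duplicated().any():
            dupes = self.counts.columns[self.counts.columns.duplicated()].tolist()
            raise ValueError(f"duplicate cell ids: {dupes}")
        if self.counts.index.duplicated().any():
            dupes = self.counts.index[self.counts.index.duplicated()].tolist()
            raise ValueError(f"duplicate gene ids: {dupes}")
        missing_cols = [c for c in REQUIRED_META_COLUMNS if c not in self.cell_meta.columns]
        if missing_cols:
            raise ValueError(f"cell_meta missing required columns: {missing_cols}")
        missing = self.counts.columns.difference(self.cell_meta.index)
        if len(missing):
            raise ValueError(
                "cells missing from metadata: " + ", ".join(map(str, missing))
            )
        extra = self.cell_meta.index.difference(self.counts.columns)
        if len(extra):
            raise ValueError(
                "metadata rows without matrix columns: " + ", ".join(map(str, extra))
            )
        # align metadata row order to the matrix column order
        self.cell_meta = self.cell_meta.loc[self.counts.columns]
        vals = self.counts.to_numpy()
        if np.isnan(vals).any():
            raise ValueError("counts contain NaN")
        if (vals < 0).any():
            raise ValueError("counts contain negative values")
        if self.gene_lengths is not None:
            self.gene_lengths = self.gene_lengths.reindex(self.counts.index)
            if self.gene_lengths.isna().any():
                raise ValueError("gene_lengths missing for some genes")
            if (self.gene_lengths <= 0).any():
                raise ValueError("gene_lengths must be positive")

    @property
    def genes(self) -> pd.Index:
        return self.counts.index

    @property
    def cells(self) -> pd.Index:
        return self.counts.columns

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    def subset_cells(self, cells) -> "ExpressionMatrix":
        cells = pd.Index(cells)
        lengths = self.gene_lengths
        return ExpressionMatrix(
            counts=self.counts[cells].copy(),
            cell_meta=self.cell_meta.loc[cells].copy(),
            gene_lengths=None if lengths is None else lengths.copy(),
        )

    def copy(self) -> "ExpressionMatrix":
        return self.subset_cells(self.cells)


@dataclass
class NormalizedMatrix:
    """Length-normalized (TPM) and log-transformed expression.

    ``tpm`` columns each sum to 1e6; ``log_expr`` is log2(TPM + pseudocount).
    ``basis`` records whether true TPM (gene lengths available) or CPM
    fallback was used.
    """

    tpm: pd.DataFrame
    log_expr: pd.DataFrame
    pseudocount: float
    cell_meta: pd.DataFrame
    basis: str = "tpm"

    def __post_init__(self) -> None:
        if self.pseudocount <= 0:
            raise ValueError("pseudocount must be positive")
        colsums = self.tpm.sum(axis=0).to_numpy()
        if not np.allclose(colsums, 1e6, rtol=1e-6):
            raise ValueError("TPM columns must sum to 1e6")
        if not np.isfinite(self.log_expr.to_numpy()).all():
            raise ValueError("log_expr must be finite")

    @property
    def genes(self) -> pd.Index:
        return self.tpm.index

    @property
    def cells(self) -> pd.Index:
        return self.tpm.columns


def _meta_path(outdir: Path) -> Path:
    return outdir / "cell_meta.tsv"


def write_expression(matrix: ExpressionMatrix, path: str | Path, format: str = "mtx") -> None:
    """Write a count matrix with its metadata to a directory.

    ``mtx`` writes matrix.mtx + genes.tsv + cells.tsv; ``tsv`` writes a
    single dense counts.tsv. Both write cell_meta.tsv and, when present,
    gene_lengths.tsv.
    """
    outdir = Path(path)
    outdir.mkdir(parents=True, exist_ok=True)
    if format == "mtx":
        sparse = scipy.sparse.csr_matrix(matrix.counts.to_numpy())
        scipy.io.mmwrite(str(outdir / "matrix.mtx"), sparse, field="integer")
        pd.Series(matrix.genes).to_csv(outdir / "genes.tsv", sep="\t", index=False, header=False)
        pd.Series(matrix.cells).to_csv(outdir / "cells.tsv", sep="\t", index=False, header=False)
    elif format == "tsv":
        matrix.counts.to_csv(outdir / "counts.tsv", sep="\t", index_label="gene")
    else:
        raise ValueError(f"unknown format: {format!r} (expected 'mtx' or 'tsv')")
    matrix.cell_meta.to_csv(_meta_path(outdir), sep="\t", index_label="cell_id")
    if matrix.gene_lengths is not None:
        matrix.gene_lengths.rename("length").to_csv(
            outdir / "gene_lengths.tsv", sep="\t", index_label="gene"
        )


def read_expression(path: str | Path, format: str = "mtx") -> ExpressionMatrix:
    """Read a count matrix written by :func:`write_expression`."""
    indir = Path(path)
    if format == "mtx":
        sparse = scipy.io.mmread(str(indir / "matrix.mtx"))
        genes = pd.read_csv(indir / "genes.tsv", sep="\t", header=None)[0]
        cells = pd.read_csv(indir / "cells.tsv", sep="\t", header=None)[0]
        counts = pd.DataFrame(
            np.asarray(sparse.todense(), dtype=np.int64), index=genes, columns=cells
        )
        counts.index.name = "gene"
    elif format == "tsv":
        counts = pd.read_csv(indir / "counts.tsv", sep="\t", index_col="gene")
        counts = counts.astype(np.int64)
    else:
        raise ValueError(f"unknown format: {format!r} (expected 'mtx' or 'tsv')")
    cell_meta = pd.read_csv(_meta_path(indir), sep="\t", index_col="cell_id")
    lengths = None
    length_path = indir / "gene_lengths.tsv"
    if length_path.exists():
        lengths = pd.read_csv(length_path, sep="\t", index_col="gene")["length"]
    return ExpressionMatrix(counts=counts, cell_meta=cell_meta, gene_lengths=lengths)
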