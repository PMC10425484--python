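"""Cell quality control and normalization.

QC drops low-quality cells on two configurable rules — a floor on detected
genes and a median-absolute-deviation outlier rule on log library size —
and reports every dropped cell with its reason. Normalization produces TPM
(length-corrected, columns summing to 1e6) when gene lengths are known,
falling back to CPM otherwise, plus log2(TPM + pseudocount).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .matrix import ExpressionMatrix, NormalizedMatrix

logger = logging.getLogger(__name__)


def qc_filter_cells(
    matrix: ExpressionMatrix,
    min_detected_genes: int = 200,
    max_mito_fraction: float | None = None,
    outlier_mad: float = 5.0,
    mito_prefix: str = "mt-",
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Drop low-quality cells; genes are never dropped here.

    A cell is removed when its number of detected genes (count > 0) falls
    below ``min_detected_genes``, when its log10 library size deviates from
    the median by more than ``outlier_mad`` scaled MADs, or (optionally)
    when its mitochondrial count fraction exceeds ``max_mito_fraction``.

    Returns the filtered matrix and a report table (cell_id, reason).
    """
    if min_detected_genes < 0 or outlier_mad < 0:
        raise ValueError("thresholds must be nonnegative")
    counts = matrix.counts
    detected = (counts > 0).sum(axis=0)
    libsize = counts.sum(axis=0).astype(float)

    reasons: dict[str, list[str]] = {}

    def _flag(cell, reason):
        reasons.setdefault(cell, []).append(reason)

    for cell in matrix.cells[detected < min_detected_genes]:
        _flag(cell, f"detected_genes<{min_detected_genes}")

    if outlier_mad > 0 and np.isfinite(outlier_mad):
        log_lib = np.log10(libsize + 1.0)
        med = np.median(log_lib)
        mad = np.median(np.abs(log_lib - med)) * 1.4826
        if mad > 0:
            dev = np.abs(log_lib - med)
            for cell in matrix.cells[dev > outlier_mad * mad]:
                _flag(cell, f"library_size_outlier>{outlier_mad}MAD")

    if max_mito_fraction is not None:
        mito_genes = [g for g in matrix.genes if str(g).lower().startswith(mito_prefix)]
        if mito_genes:
            frac = counts.loc[mito_genes].sum(axis=0) / libsize.replace(0, np.nan)
            for cell in matrix.cells[frac.fillna(0) > max_mito_fraction]:
                _flag(cell, f"mito_fraction>{max_mito_fraction}")

    dropped = sorted(reasons, key=list(matrix.cells).index)
    report = pd.DataFrame(
        {"cell_id": dropped, "reason": [";".join(reasons[c]) for c in dropped]}
    )
    keep = [c for c in matrix.cells if c not in reasons]
    if not keep:
        raise ValueError("QC removed every cell; thresholds too strict")
    if dropped:
        logger.info("QC dropped %d/%d cells", len(dropped), matrix.n_cells)
    return matrix.subset_cells(keep), report


def tpm_normalize(matrix: ExpressionMatrix, pseudocount: float = 1.0) -> NormalizedMatrix:
    """Length-normalize counts to TPM and take log2(TPM + pseudocount).

    tpm[g,c] = 1e6 * (counts[g,c]/length[g]) / sum_g'(counts[g',c]/length[g']).
    Without gene lengths, falls back to CPM (all lengths equal) with a
    logged warning. Cells with zero total counts are rejected: run
    :func:`qc_filter_cells` first.
    """
    counts = matrix.counts.to_numpy(dtype=float)
    zero_cells = matrix.cells[counts.sum(axis=0) == 0]
    if len(zero_cells):
        raise ValueError(
            "zero-count cells (run qc_filter_cells first): "
            + ", ".join(map(str, zero_cells))
        )
    basis = "tpm"
    if matrix.gene_lengths is not None:
        rate = counts / matrix.gene_lengths.to_numpy(dtype=float)[:, None]
    else:
        logger.warning("gene lengths unavailable; falling back to CPM")
        basis = "cpm"
        rate = counts
    tpm = 1e6 * rate / rate.sum(axis=0, keepdims=True)
    tpm_df = pd.DataFrame(tpm, index=matrix.genes, columns=matrix.cells)
    log_expr = np.log2(tpm_df + pseudocount)
    return NormalizedMatrix(
        tpm=tpm_df,
        log_expr=log_expr,
        pseudocount=pseudocount,
        cell_meta=matrix.cell_meta.copy(),
        basis=basis,
    )


def expressed_gene_set(
    norm: NormalizedMatrix, threshold: float = 1.0, mode: str = "max"
) -> pd.Index:
    """Genes whose max (default) or mean TPM across cells is >= threshold."""
    if threshold < 0:
        raise ValueError("threshold must be nonnegative")
    if mode == "max":
        stat = norm.tpm.max(axis=1)
    elif mode == "mean":
        stat = norm.tpm.mean(axis=1)
    else:
        raise ValueError("mode must be 'max' or 'mean'")
    return norm.genes[stat >= threshold]
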