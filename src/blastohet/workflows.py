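"""End-to-end conveniences wiring the pipeline steps together.

These helpers run the standard analysis path — normalize, pick the
expressed gene universe, build per-condition correlation matrices and
dendrogram cuts, embed, fit the developmental axis, classify — so tests,
scripts and the CLI share one code path.
"""

from __future__ import annotations

import logging

import pandas as pd

from . import classify as _classify
from . import cluster as _cluster
from .matrix import ExpressionMatrix, NormalizedMatrix
from .qc import expressed_gene_set, tpm_normalize

logger = logging.getLogger(__name__)


def condition_cluster_maps(
    norm: NormalizedMatrix,
    genes,
    k: int = 2,
    linkage: str = "average",
) -> tuple[pd.Series, pd.Series]:
    """Per-condition dendrogram cuts over all stages and over the first two.

    Returns (allstage_map, substage_map); cluster ids are prefixed with the
    condition so the combined Series stays unambiguous.
    """
    meta = norm.cell_meta
    stages_sorted = sorted(meta["stage"].unique())
    sub_stages = stages_sorted[:-1] if len(stages_sorted) > 2 else stages_sorted
    all_parts, sub_parts = [], []
    for cond in meta["condition"].unique():
        cond_cells = norm.cells[meta["condition"] == cond]
        sub_cells = cond_cells[meta.loc[cond_cells, "stage"].isin(sub_stages)]
        for cells, parts in ((cond_cells, all_parts), (sub_cells, sub_parts)):
            if len(cells) < 2:
                continue
            cm = _cluster.pearson_correlation_matrix(
                NormalizedMatrix(
                    tpm=norm.tpm[cells],
                    log_expr=norm.log_expr[cells],
                    pseudocount=norm.pseudocount,
                    cell_meta=meta.loc[cells],
                    basis=norm.basis,
                ),
                genes,
            )
            dend = _cluster.hierarchical_cluster(cm, linkage=linkage)
            labels = _cluster.cut_tree(dend, min(k, len(cm.cells)))
            parts.append(labels.map(lambda c: f"{cond}:{c}"))
    return pd.concat(all_parts), pd.concat(sub_parts)


def classification_pipeline(
    matrix: ExpressionMatrix,
    k: int | None = None,
    margin: float = 0.0,
    embedding: str = "pca",
    seed: int = 0,
    expressed_tpm: float = 1.0,
) -> _classify.CellClassification:
    """Counts -> TPM -> correlation cuts + embedding axis -> consensus labels.

    ``k`` defaults to the number of stages: one cluster per stage, with
    advanced cells landing in the next stage's cluster.
    """
    norm = tpm_normalize(matrix)
    if k is None:
        k = matrix.cell_meta["stage"].nunique()
    genes = expressed_gene_set(norm, threshold=expressed_tpm)
    allstage, substage = condition_cluster_maps(norm, genes, k=k)
    coords = _classify.embed_cells(norm, genes, method=embedding, seed=seed)
    axis = _classify.fit_developmental_axis(coords, matrix.cell_meta["stage"])
    return _classify.classify_subpopulations(
        allstage, substage, axis, matrix.cell_meta, margin=margin
    )
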