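"""Cell-cell correlation matrices, 1−r hierarchical clustering and
between-stage similarity tests.

The heterogeneity readout of the pipeline: cells are compared by the
Pearson correlation of their log2(TPM+1) profiles over an explicit gene
universe, clustered agglomeratively with distance d = 1 − r, and
between-stage similarity is summarized per cell as its mean correlation to
the cells of another stage. Higher coefficients mean more similar, less
heterogeneous populations.

The agglomeration is implemented directly (Lance–Williams updates) so the
merge order is fully specified, including the tie rule: when two candidate
merges are equally close, the lexicographically lowest cluster-index pair
merges first. The merge table uses the scipy linkage layout so scipy's
dendrogram utilities apply.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
import scipy.stats

from .matrix import NormalizedMatrix

logger = logging.getLogger(__name__)


@dataclass
class CorrelationMatrix:
    """Symmetric cell x cell Pearson r with the gene universe it used."""

    cells: pd.Index
    r: pd.DataFrame
    gene_universe: pd.Index
    dropped_cells: list

    def __post_init__(self) -> None:
        arr = self.r.to_numpy()
        if not np.allclose(arr, arr.T, atol=1e-12):
            raise ValueError("correlation matrix must be symmetric")
        if np.nanmax(np.abs(arr)) > 1 + 1e-9:
            raise ValueError("|r| must be <= 1")


@dataclass
class Dendrogram:
    """Merge history in scipy linkage layout plus leaf ids."""

    Z: np.ndarray  # (n-1, 4): left id, right id, height, size
    leaves: pd.Index  # cell ids in original order (leaf i = cluster id i)
    linkage: str

    @property
    def n_leaves(self) -> int:
        return len(self.leaves)

    def leaf_order(self) -> list:
        return [self.leaves[i] for i in sch.leaves_list(self.Z)]

    def to_newick(self) -> str:
        """Newick string with branch lengths from merge heights."""
        n = self.n_leaves
        height = {i: 0.0 for i in range(n)}
        label = {i: str(self.leaves[i]) for i in range(n)}
        for k, (a, b, h, _size) in enumerate(self.Z):
            a, b = int(a), int(b)
            la = height[a]
            lb = height[b]
            label[n + k] = f"({label[a]}:{h - la:.10g},{label[b]}:{h - lb:.10g})"
            height[n + k] = float(h)
        return label[n + self.n_leaves - 2] + ";"


@dataclass
class StageComparison:
    """Per-cell mean cross-set correlation of set_a cells against set_b."""

    set_a: pd.Index
    set_b: pd.Index
    coefficients: pd.Series  # indexed by set_a cells
    mean_r: float


def pearson_correlation_matrix(norm: NormalizedMatrix, genes) -> CorrelationMatrix:
    """Pairwise Pearson r of log expression over the given gene universe.

    Cells with zero variance over the universe have no defined correlation;
    they are excluded with a logged warning and listed in
    ``dropped_cells``.
    """
    genes = pd.Index(genes)
    if len(genes) < 2:
        raise ValueError("need at least 2 genes")
    expr = norm.log_expr.loc[genes]
    if expr.shape[1] < 2:
        raise ValueError("need at least 2 cells")
    variances = expr.var(axis=0, ddof=0)
    dropped = list(expr.columns[variances == 0])
    if dropped:
        logger.warning("dropping %d zero-variance cells from correlation: %s", len(dropped), dropped)
        expr = expr.drop(columns=dropped)
    r = np.corrcoef(expr.to_numpy(), rowvar=False)
    np.fill_diagonal(r, 1.0)
    r = np.clip(r, -1.0, 1.0)
    rdf = pd.DataFrame(r, index=expr.columns, columns=expr.columns)
    return CorrelationMatrix(cells=expr.columns, r=rdf, gene_universe=genes, dropped_cells=dropped)


def hierarchical_cluster(corr: CorrelationMatrix, linkage: str = "average") -> Dendrogram:
    """Agglomerative clustering with distance d = 1 − r.

    Deterministic: at each step the closest active pair merges; ties break
    toward the lowest (i, j) cluster-index pair. Supported linkages:
    average, complete, single.
    """
    if linkage not in ("average", "complete", "single"):
        raise ValueError(f"unsupported linkage {linkage!r}")
    cells = corr.cells
    n = len(cells)
    if n < 2:
        raise ValueError("need at least 2 cells to cluster")
    rvals = corr.r.to_numpy()
    if np.isnan(rvals).any():
        raise ValueError("correlation matrix has missing rows")
    D = 1.0 - rvals
    np.fill_diagonal(D, np.inf)

    # cluster bookkeeping: position p holds cluster id cid[p] of size sz[p]
    cid = list(range(n))
    sz = np.ones(n)
    active = np.ones(n, dtype=bool)
    W = D.copy()
    Z = np.zeros((n - 1, 4))

    for step in range(n - 1):
        mask = np.where(active)[0]
        sub = W[np.ix_(mask, mask)]
        # row-major argmin over the upper triangle = lowest (i, j) tie rule,
        # since positions are created in cluster-id order
        iu = np.triu_indices(len(mask), k=1)
        flat = sub[iu]
        best = int(np.argmin(flat))
        pi, pj = mask[iu[0][best]], mask[iu[1][best]]
        h = W[pi, pj]
        a, b = cid[pi], cid[pj]
        if a > b:
            a, b = b, a
        new_size = sz[pi] + sz[pj]
        Z[step] = (a, b, h, new_size)
        # Lance-Williams update written into position pi; pj retired
        others = active.copy()
        others[[pi, pj]] = False
        idx = np.where(others)[0]
        if linkage == "average":
            W[pi, idx] = (sz[pi] * W[pi, idx] + sz[pj] * W[pj, idx]) / new_size
        elif linkage == "complete":
            W[pi, idx] = np.maximum(W[pi, idx], W[pj, idx])
        else:  # single
            W[pi, idx] = np.minimum(W[pi, idx], W[pj, idx])
        W[idx, pi] = W[pi, idx]
        active[pj] = False
        cid[pi] = n + step
        sz[pi] = new_size
    return Dendrogram(Z=Z, leaves=cells, linkage=linkage)


def cut_tree(dend: Dendrogram, k: int) -> pd.Series:
    """Cut into exactly k clusters; ids are 1..k ordered by leaf order."""
    n = dend.n_leaves
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}]")
    parent = list(range(2 * n - 1))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for step in range(n - k):
        a, b, _h, _s = dend.Z[step]
        new = n + step
        parent[find(int(a))] = new
        parent[find(int(b))] = new
    roots = [find(i) for i in range(n)]
    # stable ids: number clusters by first appearance along the leaf order
    order = sch.leaves_list(dend.Z)
    relabel: dict[int, int] = {}
    for leaf in order:
        r = roots[leaf]
        if r not in relabel:
            relabel[r] = len(relabel) + 1
    labels = pd.Series([relabel[r] for r in roots], index=dend.leaves, name="cluster")
    return labels


def stage_similarity(corr: CorrelationMatrix, set_a, set_b) -> StageComparison:
    """Mean correlation of each set_a cell to all set_b cells."""
    set_a = pd.Index(set_a)
    set_b = pd.Index(set_b)
    if len(set_a) == 0 or len(set_b) == 0:
        raise ValueError("cell sets must be nonempty")
    if len(set_a.intersection(set_b)):
        raise ValueError("cell sets must be disjoint")
    block = corr.r.loc[set_a, set_b]
    coeff = block.mean(axis=1)
    return StageComparison(
        set_a=set_a, set_b=set_b, coefficients=coeff, mean_r=float(coeff.mean())
    )


def compare_similarity_across_conditions(
    comparisons: dict[str, StageComparison], reference: str | None = None
) -> dict:
    """ANOVA over the per-cell coefficient vectors, then pairwise Welch t.

    ``comparisons`` maps condition name -> StageComparison computed within
    that condition's correlation matrix. Returns {'F', 'p', 'posthoc'}
    where posthoc is a DataFrame of two-sided Welch t p-values for every
    pair (or each condition vs ``reference`` when given).
    """
    if len(comparisons) < 2:
        raise ValueError("need at least 2 conditions to compare")
    names = list(comparisons)
    vectors = {k: comparisons[k].coefficients.to_numpy() for k in names}
    F, p = scipy.stats.f_oneway(*vectors.values())
    if reference is not None:
        pairs = [(c, reference) for c in names if c != reference]
    else:
        pairs = [(a, b) for i, a in enumerate(names) for b in names[i + 1 :]]
    rows = []
    for a, b in pairs:
        t, pp = scipy.stats.ttest_ind(vectors[a], vectors[b], equal_var=False)
        rows.append((a, b, float(t), float(pp)))
    posthoc = pd.DataFrame(rows, columns=["group_a", "group_b", "t", "p"])
    return {"F": float(F), "p": float(p), "posthoc": posthoc}
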