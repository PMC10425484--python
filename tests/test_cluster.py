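"""Correlation matrices, 1−r agglomeration against oracles, cuts and similarity."""

import itertools

import numpy as np
import pandas as pd
import pytest
import scipy.cluster.hierarchy as sch
import scipy.spatial.distance as ssd

from blastohet import (
    compare_similarity_across_conditions,
    cut_tree,
    hierarchical_cluster,
    pearson_correlation_matrix,
    stage_similarity,
)
from blastohet.cluster import CorrelationMatrix

from conftest import make_matrix
from blastohet import tpm_normalize


def _norm_from(counts, **kw):
    return tpm_normalize(make_matrix(counts, **kw))


def _corr_from_r(r):
    n = r.shape[0]
    cells = pd.Index([f"c{i}" for i in range(n)])
    return CorrelationMatrix(
        cells=cells,
        r=pd.DataFrame(r, index=cells, columns=cells),
        gene_universe=pd.Index(["g"]),
        dropped_cells=[],
    )


def test_duplicated_and_anticorrelated_cells():
    counts = np.array([[10, 10, 1], [5, 5, 8], [1, 1, 12], [8, 8, 2]])
    norm = _norm_from(counts)
    corr = pearson_correlation_matrix(norm, norm.genes)
    assert corr.r.iloc[0, 1] == pytest.approx(1.0)
    # a profile that reverses ordering is negatively correlated
    assert corr.r.iloc[0, 2] < 0


def test_correlation_matches_hand_oracle():
    # 3 cells x 4 genes, correlation computed from the definition
    vals = np.array([[1.0, 2.0, 4.0], [3.0, 1.0, 1.0], [2.0, 5.0, 6.0], [0.0, 2.0, 3.0]])
    log_expr = pd.DataFrame(vals, index=list("abcd"), columns=["c0", "c1", "c2"])
    from blastohet.matrix import NormalizedMatrix

    tpm = pd.DataFrame(np.full((4, 3), 2.5e5), index=list("abcd"), columns=log_expr.columns)
    meta = pd.DataFrame(
        {"condition": ["WT"] * 3, "stage": [2] * 3, "embryo_id": list("xyz")},
        index=log_expr.columns,
    )
    norm = NormalizedMatrix(tpm=tpm, log_expr=log_expr, pseudocount=1.0, cell_meta=meta)
    corr = pearson_correlation_matrix(norm, log_expr.index)

    def pearson(x, y):
        x, y = x - x.mean(), y - y.mean()
        return float((x * y).sum() / np.sqrt((x**2).sum() * (y**2).sum()))

    for i, j in itertools.combinations(range(3), 2):
        expected = pearson(vals[:, i], vals[:, j])
        assert abs(corr.r.iloc[i, j] - expected) < 1e-12


def test_zero_variance_cell_dropped_with_record():
    from blastohet.matrix import NormalizedMatrix

    log_expr = pd.DataFrame(
        {"c0": [1.0, 2.0, 3.0], "c1": [2.0, 2.0, 2.0], "c2": [3.0, 1.0, 2.0]},
        index=list("abc"),
    )
    tpm = pd.DataFrame(np.full((3, 3), 1e6 / 3), index=list("abc"), columns=log_expr.columns)
    meta = pd.DataFrame(
        {"condition": ["WT"] * 3, "stage": [2] * 3, "embryo_id": list("xyz")},
        index=log_expr.columns,
    )
    norm = NormalizedMatrix(tpm=tpm, log_expr=log_expr, pseudocount=1.0, cell_meta=meta)
    corr = pearson_correlation_matrix(norm, log_expr.index)
    assert corr.dropped_cells == ["c1"]
    assert list(corr.cells) == ["c0", "c2"]


def _brute_force_average_linkage(D):
    """Exhaustive agglomeration recomputing average cross-cluster distances
    from the original matrix at every step (independent of Lance-Williams)."""
    n = D.shape[0]
    clusters = {i: [i] for i in range(n)}
    next_id = n
    merges = []
    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(sorted(clusters), 2):
            d = np.mean([D[i, j] for i in clusters[a] for j in clusters[b]])
            if best is None or d < best[0] - 1e-15:
                best = (d, a, b)
        d, a, b = best
        merges.append((a, b, d, len(clusters[a]) + len(clusters[b])))
        clusters[next_id] = clusters.pop(a) + clusters.pop(b)
        next_id += 1
    return merges


def test_merge_order_matches_brute_force_on_4_points():
    rng = np.random.default_rng(3)
    for _ in range(5):
        r = rng.uniform(-0.5, 0.9, size=(4, 4))
        r = (r + r.T) / 2
        np.fill_diagonal(r, 1.0)
        corr = _corr_from_r(r)
        dend = hierarchical_cluster(corr)
        D = 1.0 - r
        np.fill_diagonal(D, 0.0)
        expected = _brute_force_average_linkage(D)
        for step, (a, b, h, size) in enumerate(expected):
            za, zb, zh, zs = dend.Z[step]
            assert {int(za), int(zb)} == {a, b}
            assert abs(zh - h) < 1e-12
            assert zs == size


def test_linkage_matches_scipy_on_distinct_distances():
    rng = np.random.default_rng(7)
    pts = rng.normal(size=(12, 3))
    D = ssd.squareform(ssd.pdist(pts))
    r = 1.0 - D / (D.max() + 1.0)
    np.fill_diagonal(r, 1.0)
    corr = _corr_from_r(r)
    for linkage in ("average", "complete", "single"):
        ours = hierarchical_cluster(corr, linkage=linkage)
        ref = sch.linkage(ssd.squareform(1.0 - r, checks=False), method=linkage)
        assert np.allclose(np.sort(ours.Z[:, 2]), np.sort(ref[:, 2]), atol=1e-10)
        from sklearn.metrics import adjusted_rand_score

        for k in (2, 3, 5):
            a = cut_tree(ours, k)
            b = sch.fcluster(ref, k, criterion="maxclust")
            assert adjusted_rand_score(a.to_numpy(), b) == pytest.approx(1.0)


def test_tie_breaks_toward_lowest_index_pair():
    r = np.eye(4)
    r[0, 1] = r[1, 0] = 0.9
    r[2, 3] = r[3, 2] = 0.9  # tied with (0,1)
    r[0, 2] = r[2, 0] = r[0, 3] = r[3, 0] = 0.1
    r[1, 2] = r[2, 1] = r[1, 3] = r[3, 1] = 0.1
    dend = hierarchical_cluster(_corr_from_r(r))
    assert {int(dend.Z[0, 0]), int(dend.Z[0, 1])} == {0, 1}


def test_identical_pair_merges_first_at_height_zero():
    r = np.array([[1.0, 1.0, -1.0], [1.0, 1.0, -1.0], [-1.0, -1.0, 1.0]])
    dend = hierarchical_cluster(_corr_from_r(r))
    assert {int(dend.Z[0, 0]), int(dend.Z[0, 1])} == {0, 1}
    assert dend.Z[0, 2] == pytest.approx(0.0)


def test_cut_tree_extremes_and_nesting():
    rng = np.random.default_rng(1)
    r = rng.uniform(0, 0.8, size=(8, 8))
    r = (r + r.T) / 2
    np.fill_diagonal(r, 1.0)
    dend = hierarchical_cluster(_corr_from_r(r))
    assert cut_tree(dend, 1).nunique() == 1
    assert cut_tree(dend, 8).nunique() == 8
    for k in range(1, 8):
        coarse = cut_tree(dend, k)
        fine = cut_tree(dend, k + 1)
        # refinement: each fine cluster maps into exactly one coarse cluster
        mapping = pd.crosstab(fine, coarse)
        assert ((mapping > 0).sum(axis=1) == 1).all()


def test_planted_two_block_structure_recovered():
    rng = np.random.default_rng(5)
    n = 20
    r = np.full((n, n), 0.2) + rng.normal(0, 0.01, (n, n))
    r = (r + r.T) / 2
    r[:10, :10] += 0.6
    r[10:, 10:] += 0.6
    np.fill_diagonal(r, 1.0)
    r = np.clip(r, -1, 1)
    labels = cut_tree(hierarchical_cluster(_corr_from_r(r)), 2)
    assert labels.iloc[:10].nunique() == 1
    assert labels.iloc[10:].nunique() == 1
    assert labels.iloc[0] != labels.iloc[-1]


def test_newick_export_parses():
    r = np.eye(3)
    r[0, 1] = r[1, 0] = 0.8
    r[0, 2] = r[2, 0] = 0.1
    r[1, 2] = r[2, 1] = 0.1
    nwk = hierarchical_cluster(_corr_from_r(r)).to_newick()
    assert nwk.endswith(";") and nwk.count("(") == 2
    from io import StringIO

    from Bio import Phylo

    tree = Phylo.read(StringIO(nwk), "newick")
    assert tree.count_terminals() == 3


def test_stage_similarity_contracts():
    r = np.ones((4, 4))
    corr = _corr_from_r(r)
    comp = stage_similarity(corr, ["c0", "c1"], ["c2", "c3"])
    assert comp.mean_r == pytest.approx(1.0)
    assert len(comp.coefficients) == 2
    with pytest.raises(ValueError, match="disjoint"):
        stage_similarity(corr, ["c0", "c1"], ["c1", "c2"])


def test_condition_comparison_shapes():
    rng = np.random.default_rng(0)
    comps = {}
    for cond in ("WT", "KO", "TCDD"):
        r = rng.uniform(0.3, 0.9, size=(6, 6))
        r = (r + r.T) / 2
        np.fill_diagonal(r, 1.0)
        corr = _corr_from_r(r)
        comps[cond] = stage_similarity(corr, ["c0", "c1", "c2"], ["c3", "c4", "c5"])
    out = compare_similarity_across_conditions(comps, reference="WT")
    assert set(out) == {"F", "p", "posthoc"}
    assert len(out["posthoc"]) == 2  # KO vs WT, TCDD vs WT


def test_correlation_invariant_to_uniform_gene_affine_transform(small_norm):
    genes = small_norm.genes[:200]
    cells = small_norm.cells[:10]
    from blastohet.matrix import NormalizedMatrix

    base = NormalizedMatrix(
        tpm=small_norm.tpm.loc[:, cells],
        log_expr=small_norm.log_expr.loc[:, cells],
        pseudocount=1.0,
        cell_meta=small_norm.cell_meta.loc[cells],
    )
    shifted = NormalizedMatrix(
        tpm=base.tpm,
        log_expr=base.log_expr * 2.0 + 3.0,
        pseudocount=1.0,
        cell_meta=base.cell_meta,
    )
    a = pearson_correlation_matrix(base, genes).r
    b = pearson_correlation_matrix(shifted, genes).r
    assert np.allclose(a.to_numpy(), b.to_numpy(), atol=1e-12)
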