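"""Principal-tree trajectories: size factors, gene selection, MST pseudotime
and branch composition.

A transparent tree pipeline: median-of-ratios size factors, ordering-gene
selection (overdispersed genes or a provided list), PCA on size-factor-
normalized log counts, a Euclidean minimum spanning tree over cells (or
k-means centroids), pseudotime as tree path length from a root chosen
nearest the earliest stage's centroid, and branches as the segments
between nodes of degree >= 3. Branch composition is tested per
branch x label with the hypergeometric upper tail, BH-adjusted.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
import scipy.sparse.csgraph
import scipy.spatial.distance
import scipy.stats
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from .de import bh_adjust
from .matrix import ExpressionMatrix

logger = logging.getLogger(__name__)


def estimate_size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors, rescaled to geometric mean 1.

    Ratios are taken to the gene-wise geometric mean over genes expressed
    in every cell; with fewer than 50 such genes the estimate falls back to
    library-size scaling (logged).
    """
    arr = counts.to_numpy(dtype=float)
    if (arr.sum(axis=0) == 0).any():
        raise ValueError("all-zero cells present; run QC first")
    everywhere = (arr > 0).all(axis=1)
    if everywhere.sum() < 50:
        logger.warning(
            "only %d genes expressed in all cells; falling back to library-size factors",
            int(everywhere.sum()),
        )
        lib = arr.sum(axis=0)
        sf = lib / np.exp(np.mean(np.log(lib)))
    else:
        sub = arr[everywhere]
        geo = np.exp(np.mean(np.log(sub), axis=1))
        ratios = sub / geo[:, None]
        sf = np.median(ratios, axis=0)
        sf = sf / np.exp(np.mean(np.log(sf)))
    return pd.Series(sf, index=counts.columns, name="size_factor")


def select_ordering_genes(
    counts: pd.DataFrame,
    mode: str = "dispersion",
    gene_list=None,
    fdr_threshold: float = 0.1,
) -> pd.Index:
    """Genes used to order cells: overdispersed genes, or a provided list
    intersected with the expressed set."""
    expressed = counts.index[counts.sum(axis=1) > 0]
    if mode == "provided":
        if gene_list is None:
            raise ValueError("provided mode requires gene_list")
        selected = expressed.intersection(pd.Index(gene_list))
        if len(selected) == 0:
            raise ValueError("gene list disjoint from the expressed genes")
        return selected
    if mode != "dispersion":
        raise ValueError("mode must be 'dispersion' or 'provided'")
    from .hvg import call_variable_genes, fit_cv2_trend, gene_moments

    sf = estimate_size_factors(counts)
    normed = counts / sf
    moments = gene_moments(normed)
    fit = fit_cv2_trend(moments)
    table = call_variable_genes(moments, fit, fdr_threshold=fdr_threshold)
    selected = table.index[table["is_variable"].fillna(False)]
    if len(selected) == 0:
        raise ValueError("no overdispersed genes selected; provide a gene list")
    return selected


@dataclass
class TrajectoryGraph:
    """Tree over cells or centroids with pseudotime and branch labels."""

    graph: nx.Graph  # nodes = node ids; edge attr 'weight'
    root: int
    node_coords: np.ndarray  # nodes x d
    node_pseudotime: pd.Series
    node_branch: pd.Series
    cell_to_node: pd.Series  # cell id -> node id
    pseudotime: pd.Series  # per cell
    branch: pd.Series  # per cell
    granularity: str = "cell"

    @property
    def branch_points(self) -> list[int]:
        return [n for n in self.graph.nodes if self.graph.degree[n] >= 3]

    def edges_table(self) -> pd.DataFrame:
        rows = [(a, b, d["weight"]) for a, b, d in self.graph.edges(data=True)]
        return pd.DataFrame(rows, columns=["node_a", "node_b", "length"])


def _deterministic_jitter(coords: np.ndarray, ids, scale: float) -> np.ndarray:
    """Break exact coordinate duplicates with a jitter keyed by id hash."""
    out = coords.copy()
    seen: dict[bytes, int] = {}
    for i in range(out.shape[0]):
        key = out[i].tobytes()
        if key in seen:
            h = zlib.crc32(str(ids[i]).encode()) % (2**31)
            rng = np.random.default_rng(h)
            out[i] = out[i] + rng.uniform(-1, 1, out.shape[1]) * scale
            logger.warning("duplicate coordinates for %s jittered deterministically", ids[i])
        else:
            seen[key] = i
    return out


def build_trajectory(
    matrix: ExpressionMatrix,
    genes,
    d: int = 2,
    granularity: str = "cell",
    k: int | None = None,
    root_stage=None,
    seed: int = 0,
) -> TrajectoryGraph:
    """PCA + minimum-spanning-tree trajectory with root-anchored pseudotime.

    ``granularity='centroid'`` builds the tree over ``k`` k-means centroids
    and maps each cell to its nearest centroid. The root is the node
    nearest the centroid of the earliest stage (or ``root_stage``).
    """
    genes = pd.Index(genes)
    if matrix.n_cells < 3:
        raise ValueError("need at least 3 cells")
    sf = estimate_size_factors(matrix.counts)
    X = np.log2(matrix.counts.loc[genes] / sf + 1.0).to_numpy().T  # cells x genes
    d_eff = min(d, X.shape[0] - 1, X.shape[1])
    coords = PCA(n_components=d_eff, random_state=0).fit_transform(X)
    span = float(np.ptp(coords)) or 1.0
    coords = _deterministic_jitter(coords, list(matrix.cells), scale=1e-9 * span)

    stages = matrix.cell_meta["stage"]
    if root_stage is None:
        root_stage = stages.min()
    root_mask = (stages == root_stage).to_numpy()
    if not root_mask.any():
        raise ValueError(f"no cells at root stage {root_stage!r}")
    root_centroid = coords[root_mask].mean(axis=0)

    if granularity == "cell":
        node_coords = coords
        cell_to_node = pd.Series(np.arange(matrix.n_cells), index=matrix.cells)
    elif granularity == "centroid":
        if k is None or k < 2:
            raise ValueError("centroid granularity requires k >= 2")
        km = KMeans(n_clusters=k, random_state=seed, n_init=10).fit(coords)
        node_coords = km.cluster_centers_
        cell_to_node = pd.Series(km.labels_, index=matrix.cells)
    else:
        raise ValueError("granularity must be 'cell' or 'centroid'")

    root = int(np.argmin(np.linalg.norm(node_coords - root_centroid, axis=1)))
    graph, node_pt, node_branch = mst_tree(node_coords, root)
    cells = matrix.cells
    pseudotime = pd.Series(
        node_pt.loc[cell_to_node.to_numpy()].to_numpy(), index=cells, name="pseudotime"
    )
    branch = pd.Series(
        node_branch.loc[cell_to_node.to_numpy()].to_numpy(), index=cells, name="branch"
    )
    return TrajectoryGraph(
        graph=graph,
        root=root,
        node_coords=node_coords,
        node_pseudotime=node_pt,
        node_branch=node_branch,
        cell_to_node=cell_to_node,
        pseudotime=pseudotime,
        branch=branch,
        granularity=granularity,
    )


def mst_tree(node_coords: np.ndarray, root: int) -> tuple[nx.Graph, pd.Series, pd.Series]:
    """Euclidean MST over points with root-anchored pseudotime and branches.

    Returns (tree, per-node pseudotime, per-node branch label)."""
    D = scipy.spatial.distance.squareform(scipy.spatial.distance.pdist(node_coords))
    mst = scipy.sparse.csgraph.minimum_spanning_tree(D)
    graph = nx.Graph()
    graph.add_nodes_from(range(node_coords.shape[0]))
    rows, cols = mst.nonzero()
    for a, b in zip(rows, cols):
        graph.add_edge(int(a), int(b), weight=float(D[a, b]))
    assert graph.number_of_edges() == graph.number_of_nodes() - 1
    pt = nx.single_source_dijkstra_path_length(graph, root, weight="weight")
    node_pt = pd.Series({n: pt[n] for n in graph.nodes}).sort_index()
    node_branch = _branch_labels(graph, root)
    return graph, node_pt, node_branch


def _branch_labels(graph: nx.Graph, root: int) -> pd.Series:
    """Partition the tree into branch segments delimited by degree->=3 nodes.

    Non-branch-point nodes are labelled by the connected component they
    fall in once branch points are removed; each branch point inherits the
    label of its parent (toward the root), the root getting a fresh label
    when needed.
    """
    bps = {n for n in graph.nodes if graph.degree[n] >= 3}
    stripped = graph.subgraph([n for n in graph.nodes if n not in bps])
    label: dict[int, int] = {}
    for i, comp in enumerate(nx.connected_components(stripped)):
        for n in comp:
            label[n] = i
    next_label = (max(label.values()) + 1) if label else 0
    if root not in label:  # root itself is a branch point (or a lone node)
        label[root] = next_label
        next_label += 1
    # BFS from root assigns each remaining branch point its parent's label
    for parent, child in nx.bfs_edges(graph, root):
        if child not in label:
            label[child] = label[parent]
    return pd.Series({n: label[n] for n in graph.nodes}).sort_index()


@dataclass
class BranchComposition:
    table: pd.DataFrame  # branch x label counts
    tests: pd.DataFrame | None  # branch, label, overlap, p, fdr

    def enriched(self, label, alpha: float = 0.05) -> list:
        if self.tests is None:
            return []
        t = self.tests
        hits = t[(t["label"] == label) & (t["fdr"] < alpha)]
        return hits["branch"].tolist()


def branch_composition_test(traj: TrajectoryGraph, labels: pd.Series) -> BranchComposition:
    """Hypergeometric enrichment of each label in each branch.

    With a single branch only the composition table is returned."""
    labels = labels.loc[traj.pseudotime.index]
    branch = traj.branch
    table = pd.crosstab(branch, labels)
    table.index.name = "branch"
    if table.shape[0] < 2:
        return BranchComposition(table=table, tests=None)
    N = len(labels)
    rows = []
    for br in table.index:
        n_branch = int(table.loc[br].sum())
        for lab in table.columns:
            K = int((labels == lab).sum())
            kk = int(table.loc[br, lab])
            p = float(scipy.stats.hypergeom.sf(kk - 1, N, K, n_branch))
            rows.append((br, lab, kk, n_branch, K, p))
    tests = pd.DataFrame(
        rows, columns=["branch", "label", "overlap", "branch_size", "label_size", "p"]
    )
    tests["fdr"] = bh_adjust(tests["p"].to_numpy())
    return BranchComposition(table=table, tests=tests)
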