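"""Embedding, developmental axis and embryonic/differentiating classification.

Cells are embedded in 3D (seeded t-SNE, or PCA as the deterministic
fallback); a developmental axis is fitted by least-squares regression of
the numeric stage codes (2/4/8) onto the coordinates, giving every cell an
advancement score. A blastomere is called *differentiating* by consensus
between two independent indicators:

* cluster indicator — within its condition, the cell sits in the
  "advanced" cluster of the 1−r dendrogram cut (the cluster whose members
  have the highest mean advancement score, in practice the one carrying
  the next stage's cells);
* position indicator — its own advancement score exceeds its stage
  centroid by at least ``margin`` x the gap to the next stage's centroid.

Cells where the two indicators disagree are *excluded* with a recorded
mismatch reason, mirroring how visually inconsistent blastomeres are left
out of subpopulation analyses. Cells of the last stage have no next stage
to advance toward and are labelled embryonic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
from sklearn.decomposition import PCA
from sklearn.manifold import TSNE

from .matrix import NormalizedMatrix

logger = logging.getLogger(__name__)


@dataclass
class EmbeddingCoords:
    cells: pd.Index
    coords: pd.DataFrame  # cells x components
    method: str
    seed: int


@dataclass
class DevelopmentalAxis:
    direction: np.ndarray  # unit vector in embedding space
    scores: pd.Series  # per-cell advancement score (projection)
    stage_centroids: pd.Series  # mean score per stage, sorted by stage


@dataclass
class CellClassification:
    table: pd.DataFrame  # cell x (label, cluster_id, advancement_score, condition, stage, reason)

    @property
    def labels(self) -> pd.Series:
        return self.table["label"]


@dataclass
class SubpopulationCounts:
    counts: pd.DataFrame  # per group: n_embryonic, n_differentiating, n_excluded, percent_differentiating
    tests: pd.DataFrame | None  # per stage: F, p + post-hoc vs reference


def embed_cells(
    norm: NormalizedMatrix,
    genes,
    method: str = "pca",
    seed: int = 0,
    n_components: int = 3,
    perplexity: float = 30.0,
) -> EmbeddingCoords:
    """3D embedding of cells on the given gene universe.

    ``pca`` is deterministic; ``tsne`` is stochastic but fully seeded.
    """
    genes = pd.Index(genes)
    if len(genes) < n_components:
        raise ValueError("need at least as many genes as components")
    X = norm.log_expr.loc[genes].to_numpy().T  # cells x genes
    if X.shape[0] < n_components:
        raise ValueError("fewer cells than components")
    if method == "pca":
        coords = PCA(n_components=n_components, random_state=0).fit_transform(X)
    elif method == "tsne":
        perplexity = min(perplexity, (X.shape[0] - 1) / 3.0)
        coords = TSNE(
            n_components=n_components,
            random_state=seed,
            perplexity=perplexity,
            init="pca",
        ).fit_transform(X)
    else:
        raise ValueError("method must be 'pca' or 'tsne'")
    cdf = pd.DataFrame(
        coords, index=norm.cells, columns=[f"dim{i + 1}" for i in range(n_components)]
    )
    return EmbeddingCoords(cells=norm.cells, coords=cdf, method=method, seed=seed)


def fit_developmental_axis(coords: EmbeddingCoords, stages: pd.Series) -> DevelopmentalAxis:
    """Least-squares fit of stage codes onto coordinates.

    The direction is the normalized regression vector of the numeric stage
    codes (2/4/8) on the centered embedding; the advancement score is the
    projection onto it. Fails loudly when the per-stage centroid scores are
    not strictly increasing with stage.
    """
    stages = stages.loc[coords.cells]
    X = coords.coords.to_numpy()
    Xc = X - X.mean(axis=0)
    if np.allclose(Xc, 0):
        raise ValueError("degenerate coordinates: zero variance")
    y = stages.to_numpy(dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("need at least 2 stages to fit an axis")
    beta, *_ = np.linalg.lstsq(Xc, y - y.mean(), rcond=None)
    norm_beta = np.linalg.norm(beta)
    if norm_beta == 0:
        raise ValueError("axis fit degenerate: stages unrelated to coordinates")
    direction = beta / norm_beta
    scores = pd.Series(Xc @ direction, index=coords.cells, name="advancement_score")
    centroids = scores.groupby(stages).mean().sort_index()
    if not np.all(np.diff(centroids.to_numpy()) > 0):
        raise ValueError(
            "developmental axis fit failed: stage centroids not strictly increasing "
            f"({centroids.to_dict()})"
        )
    return DevelopmentalAxis(direction=direction, scores=scores, stage_centroids=centroids)


def classify_subpopulations(
    cluster_map_allstage: pd.Series,
    cluster_map_substage: pd.Series | None,
    axis: DevelopmentalAxis,
    meta: pd.DataFrame,
    margin: float = 0.0,
) -> CellClassification:
    """Consensus embryonic/differentiating labels per cell.

    ``cluster_map_allstage`` covers every cell (dendrogram cut of the
    all-stage correlation matrix); ``cluster_map_substage`` covers the
    cells of the first two stages (cut of the 2-and-4-cell matrix) and is
    used for the earliest stage boundary. Cluster ids only need to be
    consistent within a condition.
    """
    cells = axis.scores.index
    missing = cells.difference(cluster_map_allstage.index)
    if len(missing):
        raise ValueError("all-stage cluster map missing cells: " + ", ".join(map(str, missing)))
    meta = meta.loc[cells]
    stages_sorted = sorted(meta["stage"].unique())
    centroids = axis.stage_centroids

    label = pd.Series("embryonic", index=cells, name="label")
    reason = pd.Series("", index=cells, name="reason")
    cluster_used = pd.Series(np.nan, index=cells, name="cluster_id", dtype=object)

    for cond in meta["condition"].unique():
        cond_cells = cells[meta["condition"] == cond]
        for si, stage in enumerate(stages_sorted[:-1]):
            nxt = stages_sorted[si + 1]
            use_substage = (
                cluster_map_substage is not None
                and si + 1 < len(stages_sorted) - 1  # boundary not into the last stage
            )
            cmap = cluster_map_substage if use_substage else cluster_map_allstage
            covered = cond_cells.intersection(cmap.index)
            stage_cells = cond_cells[meta.loc[cond_cells, "stage"] == stage]
            stage_cells = stage_cells.intersection(cmap.index)
            if len(stage_cells) == 0:
                continue
            cluster_used.loc[stage_cells] = cmap.loc[stage_cells].to_numpy()
            cond_clusters = cmap.loc[covered]
            if cond_clusters.nunique() < 2:
                logger.info(
                    "condition %s stage %s: single cluster, all embryonic", cond, stage
                )
                continue
            gap = centroids.loc[nxt] - centroids.loc[stage]
            # a cluster counts as advanced for this boundary when its mean
            # advancement score lies beyond the midpoint to the next stage
            mean_scores = axis.scores.loc[covered].groupby(cond_clusters).mean()
            midpoint = centroids.loc[stage] + 0.5 * gap
            advanced_clusters = set(mean_scores.index[mean_scores >= midpoint])
            if not advanced_clusters:
                continue
            in_advanced = cmap.loc[stage_cells].isin(advanced_clusters)
            if in_advanced.mean() > 0.5:
                # an advanced subpopulation is by definition a minority that
                # segregates away from its stage; a cut placing most of the
                # stage in advanced clusters isolated nothing
                logger.info(
                    "condition %s stage %s: advanced clusters hold %.0f%% of the "
                    "stage, no advanced subpopulation isolated",
                    cond, stage, 100 * in_advanced.mean(),
                )
                continue
            threshold = centroids.loc[stage] + margin * gap
            above = axis.scores.loc[stage_cells] >= threshold
            diff_mask = in_advanced & above
            mismatch_cluster = in_advanced & ~above
            mismatch_position = ~in_advanced & above
            label.loc[stage_cells[diff_mask]] = "differentiating"
            label.loc[stage_cells[mismatch_cluster]] = "excluded"
            reason.loc[stage_cells[mismatch_cluster]] = (
                "cluster/position mismatch: advanced cluster, below stage centroid"
            )
            label.loc[stage_cells[mismatch_position]] = "excluded"
            reason.loc[stage_cells[mismatch_position]] = (
                "cluster/position mismatch: above centroid, non-advanced cluster"
            )

    # last-stage cells keep the cluster they fell in, for provenance
    last_cells = cells[meta["stage"] == stages_sorted[-1]]
    cluster_used.loc[last_cells] = cluster_map_allstage.loc[last_cells].to_numpy()

    table = pd.DataFrame(
        {
            "label": label,
            "cluster_id": cluster_used,
            "advancement_score": axis.scores,
            "condition": meta["condition"],
            "stage": meta["stage"],
            "reason": reason,
        }
    )
    return CellClassification(table=table)


def differentiating_fraction_test(
    classification: CellClassification,
    meta: pd.DataFrame,
    reference: str = "WT",
) -> SubpopulationCounts:
    """Group counts and per-stage tests of differentiating fractions.

    The statistical unit is the embryo: per-embryo differentiating
    fractions feed a one-way ANOVA across conditions at each stage,
    followed by Welch t post-hoc tests against the reference condition.
    Conditions with fewer than two embryos are skipped with a warning.
    """
    tab = classification.table.join(meta[["embryo_id"]])
    counts = (
        tab.groupby(["condition", "stage"])["label"]
        .value_counts()
        .unstack(fill_value=0)
        .reindex(columns=["embryonic", "differentiating", "excluded"], fill_value=0)
    )
    counts.columns = [f"n_{c}" for c in counts.columns]
    total = counts.sum(axis=1)
    counts["percent_differentiating"] = 100.0 * counts["n_differentiating"] / total

    embryo_frac = (
        tab.assign(is_diff=tab["label"] == "differentiating")
        .groupby(["condition", "stage", "embryo_id"])["is_diff"]
        .mean()
    )
    conditions = tab["condition"].unique()
    rows = []
    if len(conditions) >= 2:
        for stage in sorted(tab["stage"].unique()):
            groups = {}
            for cond in conditions:
                try:
                    vals = embryo_frac.loc[(cond, stage)].to_numpy()
                except KeyError:
                    continue
                if len(vals) < 2:
                    logger.warning("condition %s stage %s has <2 embryos; skipped", cond, stage)
                    continue
                groups[cond] = vals
            if len(groups) < 2:
                continue
            allvals = np.concatenate(list(groups.values()))
            if np.allclose(allvals, allvals[0]):
                F, p = 0.0, 1.0
            else:
                F, p = scipy.stats.f_oneway(*groups.values())
            for cond, vals in groups.items():
                if cond == reference or reference not in groups:
                    continue
                ref = groups[reference]
                both = np.concatenate([vals, ref])
                if np.allclose(both, both[0]):
                    t, pp = 0.0, 1.0
                else:
                    t, pp = scipy.stats.ttest_ind(vals, ref, equal_var=False)
                    if np.isnan(pp):  # zero variance on both sides, unequal means
                        t, pp = np.inf, 0.0
                rows.append((stage, cond, reference, float(F), float(p), float(t), float(pp)))
    tests = (
        pd.DataFrame(
            rows,
            columns=["stage", "condition", "reference", "anova_F", "anova_p", "t", "posthoc_p"],
        )
        if rows
        else None
    )
    return SubpopulationCounts(counts=counts, tests=tests)
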