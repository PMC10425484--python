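"""Differential expression, FDR adjustment, overlap tests and dot-plot stats.

DE between two cell groups defaults to per-gene Welch t on log2(TPM+1)
(Wilcoxon rank-sum optional), with Benjamini–Hochberg adjustment. The
significance of a variable-gene / DE-gene overlap is the hypergeometric
upper tail within an explicit gene universe (identical to a one-sided
Fisher exact test on the 2x2 table). Per-gene group statistics follow the
dot-plot convention: one-way ANOVA over all groups, then requested
pairwise Welch t contrasts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multitest import multipletests

from .matrix import NormalizedMatrix

logger = logging.getLogger(__name__)


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (monotone in p)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def differential_expression(
    norm: NormalizedMatrix, cells_a, cells_b, method: str = "welch_t"
) -> pd.DataFrame:
    """Per-gene two-group test on log2(TPM+1) with BH adjustment.

    Returns mean_a, mean_b, lfc = mean_a − mean_b (log2 units), p, fdr.
    Genes constant and equal across both groups get p = 1.
    """
    cells_a, cells_b = pd.Index(cells_a), pd.Index(cells_b)
    if len(cells_a) < 2 or len(cells_b) < 2:
        raise ValueError("need at least 2 cells per group")
    A = norm.log_expr[cells_a].to_numpy()
    B = norm.log_expr[cells_b].to_numpy()
    mean_a = A.mean(axis=1)
    mean_b = B.mean(axis=1)
    lfc = mean_a - mean_b
    if method == "welch_t":
        with np.errstate(invalid="ignore", divide="ignore"):
            _t, p = scipy.stats.ttest_ind(A, B, axis=1, equal_var=False)
    elif method == "wilcoxon":
        p = np.array(
            [scipy.stats.mannwhitneyu(A[i], B[i], alternative="two-sided").pvalue
             for i in range(A.shape[0])]
        )
    else:
        raise ValueError("method must be 'welch_t' or 'wilcoxon'")
    degenerate = (A.var(axis=1) == 0) & (B.var(axis=1) == 0)
    p = np.where(degenerate & (mean_a == mean_b), 1.0, p)
    p = np.where(degenerate & (mean_a != mean_b), 0.0, p)
    p = np.nan_to_num(p, nan=1.0)
    out = pd.DataFrame(
        {"mean_a": mean_a, "mean_b": mean_b, "lfc": lfc, "p": p}, index=norm.genes
    )
    out["fdr"] = bh_adjust(out["p"].to_numpy())
    return out


@dataclass
class OverlapResult:
    n_vg: int
    n_de: int
    n_overlap: int
    n_universe: int
    p: float


def overlap_test(vg, de, universe) -> OverlapResult:
    """Hypergeometric upper-tail significance of |vg ∩ de| in the universe."""
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    vg, de = set(vg), set(de)
    if not vg <= universe or not de <= universe:
        raise ValueError("vg and de must be subsets of the universe")
    k = len(vg & de)
    N, K, n = len(universe), len(vg), len(de)
    p = float(scipy.stats.hypergeom.sf(k - 1, N, K, n))
    return OverlapResult(n_vg=K, n_de=n, n_overlap=k, n_universe=N, p=p)


@dataclass
class GroupStats:
    gene: str
    group_means: pd.Series
    anova_F: float
    anova_p: float
    posthoc: pd.DataFrame  # contrast code, group_a, group_b, t, p, note


def groupwise_anova(
    norm: NormalizedMatrix,
    gene: str,
    grouping: pd.Series,
    contrasts: list[tuple[str, str, str]],
) -> GroupStats:
    """One-way ANOVA on log2(TPM+1) for one gene, plus named Welch contrasts.

    ``contrasts`` is a list of (code, group_a, group_b) — e.g. the dot-plot
    codes '*' (vs control bulk) or '#' (vs precedent stage). Contrasts
    naming a missing group are skipped with a note.
    """
    values = norm.log_expr.loc[gene]
    grouping = grouping.loc[values.index]
    groups = {g: values[grouping == g].to_numpy() for g in grouping.unique()}
    groups = {g: v for g, v in groups.items() if len(v) >= 2}
    if len(groups) < 2:
        raise ValueError("need at least 2 groups with >= 2 cells each")
    allvals = np.concatenate(list(groups.values()))
    if np.allclose(allvals, allvals[0]):
        F, p = 0.0, 1.0
    else:
        F, p = scipy.stats.f_oneway(*groups.values())
    rows = []
    for code, a, b in contrasts:
        if a not in groups or b not in groups:
            rows.append((code, a, b, np.nan, np.nan, "skipped: missing group"))
            continue
        both = np.concatenate([groups[a], groups[b]])
        if np.allclose(both, both[0]):
            t, pp = 0.0, 1.0
        else:
            t, pp = scipy.stats.ttest_ind(groups[a], groups[b], equal_var=False)
            if np.isnan(pp):
                t, pp = np.inf, 0.0
        rows.append((code, a, b, float(t), float(pp), ""))
    posthoc = pd.DataFrame(rows, columns=["code", "group_a", "group_b", "t", "p", "note"])
    means = pd.Series({g: v.mean() for g, v in groups.items()}, name="mean")
    return GroupStats(gene=gene, group_means=means, anova_F=float(F), anova_p=float(p), posthoc=posthoc)


def dotplot_contrasts(
    groups: list[str], reference_condition: str = "WT", sep: str = ":"
) -> list[tuple[str, str, str]]:
    """Standard dot-plot contrast presets from 'condition:stage[:subpop]' labels.

    Codes: '*' condition bulk vs reference bulk at the same stage;
    '#' bulk vs the precedent stage of the same condition;
    'a'/'b' subpopulation vs the reference embryonic/differentiating
    subpopulation of the same stage; 'c' embryonic vs differentiating within
    the same group; 'd' subpopulation vs the embryonic subpopulation of the
    precedent stage of the same condition.
    """
    parsed = [tuple(g.split(sep)) for g in groups]
    stages = sorted({int(p[1]) for p in parsed})
    prev = {s: stages[i - 1] for i, s in enumerate(stages) if i > 0}
    out = []
    for parts in parsed:
        if len(parts) == 2:
            cond, stage = parts
            g = f"{cond}{sep}{stage}"
            ref = f"{reference_condition}{sep}{stage}"
            if cond != reference_condition and ref in groups:
                out.append(("*", g, ref))
            s = int(stage)
            if s in prev:
                pg = f"{cond}{sep}{prev[s]}"
                if pg in groups:
                    out.append(("#", g, pg))
        elif len(parts) == 3:
            cond, stage, sub = parts
            g = f"{cond}{sep}{stage}{sep}{sub}"
            ref_emb = f"{reference_condition}{sep}{stage}{sep}embryonic"
            ref_diff = f"{reference_condition}{sep}{stage}{sep}differentiating"
            if cond != reference_condition:
                if ref_emb in groups:
                    out.append(("a", g, ref_emb))
                if ref_diff in groups:
                    out.append(("b", g, ref_diff))
            if sub == "differentiating":
                emb = f"{cond}{sep}{stage}{sep}embryonic"
                if emb in groups:
                    out.append(("c", g, emb))
            s = int(stage)
            if s in prev:
                pe = f"{cond}{sep}{prev[s]}{sep}embryonic"
                if pe in groups:
                    out.append(("d", g, pe))
    return out
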