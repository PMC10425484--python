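"""Synthetic blastomere scRNA-seq counts with planted ground truth.

The generator emulates the study design the analysis pipeline expects:
three conditions (wild type, receptor knockout, dioxin-exposed) x three
cleavage stages (2-, 4-, 8-cell), eight embryos per group, and one cell
per blastomere (2/4/8 cells per embryo -> 336 cells at defaults). Counts
are negative-binomial (gamma-Poisson) with log-normal gene means,
log-uniform gene-level dispersion and log-normal per-cell depth factors.

Structure planted on top of the null:

* cumulative stage programs — a block of genes is up-shifted at the 4-cell
  stage and a second block additionally at the 8-cell stage;
* a minority "differentiating" subpopulation in selected condition x stage
  groups, which receives its own program plus a configurable fraction of
  the next stage's program (so the cells are genuinely advanced along the
  developmental axis, as the biology implies);
* per-cell log-normal noise on program-gene means whose standard deviation
  is scaled per condition (``heterogeneity_scale`` < 1 produces the more
  homogeneous, more tightly correlated state);
* marker genes whose group means follow receptor/pluripotency/trophoblast
  profiles (high-early declining; high-dip-high with knockout reduction;
  late-only with knockout reduction);
* a handful of planted low-depth cells for QC to catch.

Everything random flows from a single seed; a fixed seed gives
byte-identical output.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .matrix import ExpressionMatrix

logger = logging.getLogger(__name__)

GENE_CLASSES = ("stage-program", "diff-program", "variable", "marker", "null")


def default_marker_profiles() -> pd.DataFrame:
    """Qualitative marker means per (gene, condition, stage, subpopulation).

    Ahr: highest at the 2-cell stage and declining thereafter; near-absent
    in the knockout; lower in the differentiating subpopulation. Oct4
    (Pou5f1): high -> dip at 4-cell -> high at 8-cell, reduced in KO/TCDD.
    Cdx2: essentially off before the 8-cell stage, high at 8-cell, reduced
    in the knockout. Units are expected counts.
    """
    base = {
        "Ahr": {2: 120.0, 4: 60.0, 8: 30.0},
        "Pou5f1": {2: 100.0, 4: 40.0, 8: 120.0},
        "Cdx2": {2: 1.0, 4: 1.0, 8: 80.0},
    }
    cond_factor = {
        "Ahr": {"WT": 1.0, "KO": 0.05, "TCDD": 1.0},
        "Pou5f1": {"WT": 1.0, "KO": 0.5, "TCDD": 0.5},
        "Cdx2": {"WT": 1.0, "KO": 0.25, "TCDD": 0.8},
    }
    # differentiating blastomeres are receptor-low / pluripotency-low
    diff_factor = {"Ahr": 0.4, "Pou5f1": 0.4, "Cdx2": 1.5}
    rows = []
    for gene, stage_means in base.items():
        for cond in ("WT", "KO", "TCDD"):
            for stage, mean in stage_means.items():
                m = mean * cond_factor[gene][cond]
                rows.append((gene, cond, stage, "embryonic", m))
                rows.append((gene, cond, stage, "differentiating", m * diff_factor[gene]))
    return pd.DataFrame(
        rows, columns=["gene", "condition", "stage", "subpopulation", "mean"]
    )


@dataclass
class SimulationConfig:
    """Knobs of the synthetic blastomere experiment (defaults = study design)."""

    n_genes: int = 2000
    n_embryos_per_group: int = 8
    conditions: tuple[str, ...] = ("WT", "KO", "TCDD")
    stages: tuple[int, ...] = (2, 4, 8)
    nb_dispersion: float = 5.0  # scales the log-uniform gene-level NB size
    baseline_mean_log: float = 3.0  # natural-log mean of log-normal gene means
    baseline_mean_sd: float = 1.5
    stage_program_size: int = 200
    stage_lfc: float = 2.0  # log2 fold change per stage transition
    last_transition_weight: int = 4  # size multiplier for the final stage program
    diff_fraction: dict = field(
        default_factory=lambda: {("WT", 4): 0.25, ("TCDD", 4): 0.10, ("KO", 4): 0.0}
    )
    diff_program_size: int = 200
    diff_lfc: float = 2.0
    diff_stage_advance: float = 1.0  # fraction of next-stage program applied
    heterogeneity_scale: dict = field(
        default_factory=lambda: {"WT": 1.0, "KO": 0.5, "TCDD": 0.5}
    )
    heterogeneity_sd: float = 0.8  # log-e sd of per-cell program noise at scale 1
    heterogeneity_stage_onset: int = 4  # first stage at which program noise appears
    marker_profiles: pd.DataFrame | None = None
    gene_length_range: tuple[int, int] = (500, 10000)
    depth_sd: float = 0.05  # log-normal sd of per-cell depth factors (depth-equalized pools)
    n_low_quality_cells: int = 0
    low_quality_factor: float = 0.01
    seed: int = 0

    def validate(self) -> None:
        grid = {(c, s) for c in self.conditions for s in self.stages}
        for key, frac in self.diff_fraction.items():
            if tuple(key) not in grid:
                raise ValueError(f"diff_fraction group {key!r} not in the condition x stage grid")
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"diff_fraction[{key!r}]={frac} outside [0, 1]")
        for cond in self.conditions:
            if self.heterogeneity_scale.get(cond, 1.0) <= 0:
                raise ValueError("heterogeneity_scale values must be positive")
        if self.n_genes < 2 * self.stage_program_size + self.diff_program_size:
            raise ValueError("n_genes too small for the requested programs")
        if self.nb_dispersion <= 0 or self.depth_sd < 0:
            raise ValueError("nb_dispersion must be positive, depth_sd nonnegative")


@dataclass
class TruthLabels:
    """Planted ground truth: per-cell subpopulation and per-gene class."""

    cell_labels: pd.Series  # embryonic | differentiating
    gene_classes: pd.Series  # stage-program | diff-program | variable | marker | null
    depth_factors: pd.Series = None
    low_quality_cells: pd.Index = None
    programs: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.cell_labels.index.duplicated().any():
            raise ValueError("duplicate cell ids in truth labels")
        if self.gene_classes.index.duplicated().any():
            raise ValueError("duplicate gene ids in truth labels")
        bad = set(self.gene_classes.unique()) - set(GENE_CLASSES)
        if bad:
            raise ValueError(f"unknown gene classes: {bad}")


def _cell_table(config: SimulationConfig) -> pd.DataFrame:
    rows = []
    for cond in config.conditions:
        for stage in config.stages:
            for embryo in range(1, config.n_embryos_per_group + 1):
                for cell in range(1, stage + 1):
                    cid = f"{cond}_s{stage}_e{embryo:02d}_c{cell}"
                    rows.append((cid, cond, stage, f"{cond}_s{stage}_e{embryo:02d}"))
    return pd.DataFrame(
        rows, columns=["cell_id", "condition", "stage", "embryo_id"]
    ).set_index("cell_id")


def simulate_counts(config: SimulationConfig) -> tuple[ExpressionMatrix, TruthLabels]:
    """Draw one synthetic blastomere count matrix plus its ground truth."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    markers = (
        config.marker_profiles
        if config.marker_profiles is not None
        else default_marker_profiles()
    )
    marker_genes = list(dict.fromkeys(markers["gene"]))
    n_background = config.n_genes - len(marker_genes)
    n_transitions = len(config.stages) - 1
    w = config.last_transition_weight if n_transitions > 1 else 1
    program_genes_needed = (
        config.stage_program_size * (n_transitions - 1 + w) + config.diff_program_size
    )
    if n_background < program_genes_needed:
        raise ValueError("n_genes too small after reserving marker and program genes")
    width = len(str(n_background))
    genes = [f"g{i + 1:0{width}d}" for i in range(n_background)] + marker_genes
    gene_index = pd.Index(genes, name="gene")

    meta = _cell_table(config)
    cells = meta.index
    n_cells = len(cells)
    stages_sorted = sorted(config.stages)

    # gene-level null parameters
    mu = rng.lognormal(config.baseline_mean_log, config.baseline_mean_sd, config.n_genes)
    size = config.nb_dispersion * np.exp(
        rng.uniform(np.log(1.0), np.log(10.0), config.n_genes)
    )
    lengths = pd.Series(
        rng.integers(config.gene_length_range[0], config.gene_length_range[1] + 1, config.n_genes),
        index=gene_index,
        name="length",
    )

    # disjoint program gene sets drawn from the background genes; later
    # transitions remodel more genes (the final one twice the base size),
    # so the last stage splits off first in correlation space
    perm = rng.permutation(n_background)
    s = config.stage_program_size
    programs: dict = {}
    offset = 0
    transitions = stages_sorted[1:]
    for i, stage in enumerate(transitions):
        last = i == len(transitions) - 1 and len(transitions) > 1
        size_i = config.last_transition_weight * s if last else s
        programs[f"stage{stage}"] = gene_index[perm[offset : offset + size_i]]
        offset += size_i
    programs["diff"] = gene_index[perm[offset : offset + config.diff_program_size]]

    gene_classes = pd.Series("null", index=gene_index, name="gene_class")
    for key, idx in programs.items():
        gene_classes.loc[idx] = "diff-program" if key == "diff" else "stage-program"
    gene_classes.loc[marker_genes] = "marker"

    # per-cell subpopulation truth
    cell_labels = pd.Series("embryonic", index=cells, name="subpopulation")
    for (cond, stage), frac in config.diff_fraction.items():
        group_cells = cells[(meta["condition"] == cond) & (meta["stage"] == stage)]
        n_diff = int(round(frac * len(group_cells)))
        if n_diff:
            chosen = rng.choice(group_cells, size=n_diff, replace=False)
            cell_labels.loc[chosen] = "differentiating"

    # expected-mean matrix: baseline, then cumulative stage programs,
    # then differentiating-cell shifts
    M = np.tile(mu[:, None], (1, n_cells))
    gpos = {g: i for i, g in enumerate(gene_index)}
    stage_arr = meta["stage"].to_numpy()
    cond_arr = meta["condition"].to_numpy()
    is_diff = (cell_labels == "differentiating").to_numpy()

    for i, stage in enumerate(stages_sorted[1:]):
        rows = [gpos[g] for g in programs[f"stage{stage}"]]
        cols = stage_arr >= stage
        M[np.ix_(rows, cols)] *= 2.0 ** config.stage_lfc

    diff_rows = [gpos[g] for g in programs["diff"]]
    for j, cid in enumerate(cells):
        if not is_diff[j]:
            continue
        M[diff_rows, j] *= 2.0 ** config.diff_lfc
        stage = stage_arr[j]
        k = stages_sorted.index(stage)
        if k + 1 < len(stages_sorted):
            nxt = stages_sorted[k + 1]
            rows = [gpos[g] for g in programs[f"stage{nxt}"]]
            M[rows, j] *= 2.0 ** (config.diff_stage_advance * config.stage_lfc)

    # marker override: deterministic in the mean
    sub_arr = cell_labels.to_numpy()
    lookup = markers.set_index(["gene", "condition", "stage", "subpopulation"])["mean"]
    for g in marker_genes:
        row = gpos[g]
        for j in range(n_cells):
            M[row, j] = lookup[(g, cond_arr[j], int(stage_arr[j]), sub_arr[j])]

    # per-cell log-normal heterogeneity on program genes, mean-one, scaled
    # per condition; inter-blastomere noise only appears from the onset
    # stage onward (early cleavage cells are transcriptionally homogeneous)
    het_rows = sorted(
        {gpos[g] for key in programs for g in programs[key]}
    )
    scale = np.array([config.heterogeneity_scale.get(c, 1.0) for c in cond_arr])
    onset = (stage_arr >= config.heterogeneity_stage_onset).astype(float)
    sd = config.heterogeneity_sd * scale * onset  # per cell
    noise = rng.normal(0.0, 1.0, (len(het_rows), n_cells)) * sd[None, :]
    M[het_rows, :] *= np.exp(noise - 0.5 * sd[None, :] ** 2)

    # per-cell depth factors, with optional planted low-depth cells
    depth = rng.lognormal(0.0, config.depth_sd, n_cells)
    low_quality = pd.Index([])
    if config.n_low_quality_cells:
        chosen = rng.choice(cells, size=config.n_low_quality_cells, replace=False)
        low_quality = pd.Index(sorted(chosen, key=list(cells).index))
        depth[[list(cells).index(c) for c in low_quality]] *= config.low_quality_factor

    # gamma-Poisson = negative binomial with gene-level size
    lam = rng.gamma(shape=size[:, None], scale=(M * depth[None, :]) / size[:, None])
    counts = rng.poisson(lam).astype(np.int64)

    matrix = ExpressionMatrix(
        counts=pd.DataFrame(counts, index=gene_index, columns=cells),
        cell_meta=meta,
        gene_lengths=lengths,
    )
    truth = TruthLabels(
        cell_labels=cell_labels,
        gene_classes=gene_classes,
        depth_factors=pd.Series(depth, index=cells, name="depth_factor"),
        low_quality_cells=low_quality,
        programs=programs,
    )
    return matrix, truth


def inject_variable_genes(
    matrix: ExpressionMatrix,
    n: int,
    cv2_inflation: float,
    seed: int,
    truth: TruthLabels | None = None,
) -> tuple[ExpressionMatrix, TruthLabels]:
    """Resample ``n`` null genes so their CV² sits ~``cv2_inflation`` x the trend.

    The matrix's own mean-CV² trend is fitted first; each injected gene is
    redrawn gamma-Poisson with the extra-Poisson variance set to hit the
    inflated target at its current mean. Genes whose mean is so low that
    the target falls below the Poisson floor are relabelled in the truth
    but cannot be made (or detected as) super-trend; they are redrawn as
    plain Poisson.
    """
    from .hvg import fit_cv2_trend, gene_moments

    if cv2_inflation <= 1.0:
        raise ValueError("cv2_inflation must exceed 1 (otherwise not super-trend)")
    if n > matrix.n_genes:
        raise ValueError("cannot inject more genes than the matrix has")

    gene_classes = (
        truth.gene_classes.copy()
        if truth is not None
        else pd.Series("null", index=matrix.genes, name="gene_class")
    )
    cell_labels = (
        truth.cell_labels.copy()
        if truth is not None
        else pd.Series("embryonic", index=matrix.cells, name="subpopulation")
    )
    if n == 0:
        return matrix.copy(), TruthLabels(
            cell_labels=cell_labels,
            gene_classes=gene_classes,
            depth_factors=None if truth is None else truth.depth_factors,
            low_quality_cells=None if truth is None else truth.low_quality_cells,
            programs={} if truth is None else truth.programs,
        )

    rng = np.random.default_rng(seed)
    null_genes = gene_classes.index[gene_classes == "null"]
    if len(null_genes) < n:
        raise ValueError(f"only {len(null_genes)} null genes available, asked for {n}")
    chosen = rng.choice(null_genes, size=n, replace=False)

    counts = matrix.counts.copy()
    moments = gene_moments(counts.astype(float))
    fit = fit_cv2_trend(moments)
    n_cells = matrix.n_cells

    for g in chosen:
        mu_g = float(moments.loc[g, "mu"])
        if mu_g <= 0:
            logger.warning("gene %s has zero mean; labelled but left untouched", g)
            gene_classes.loc[g] = "variable"
            continue
        target = cv2_inflation * float(fit.trend(mu_g))
        excess = target - 1.0 / mu_g  # extra-Poisson CV² needed
        if excess <= 0:
            # target below the Poisson floor: cannot be made super-trend
            logger.warning(
                "gene %s: mean %.3g too low; injection undetectable", g, mu_g
            )
            new = rng.poisson(mu_g, n_cells)
        else:
            shape = 1.0 / excess
            lam = rng.gamma(shape=shape, scale=mu_g / shape, size=n_cells)
            new = rng.poisson(lam)
        counts.loc[g] = new
        gene_classes.loc[g] = "variable"

    new_matrix = ExpressionMatrix(
        counts=counts,
        cell_meta=matrix.cell_meta.copy(),
        gene_lengths=None if matrix.gene_lengths is None else matrix.gene_lengths.copy(),
    )
    new_truth = TruthLabels(
        cell_labels=cell_labels,
        gene_classes=gene_classes,
        depth_factors=None if truth is None else truth.depth_factors,
        low_quality_cells=None if truth is None else truth.low_quality_cells,
        programs={} if truth is None else truth.programs,
    )
    return new_matrix, new_truth


def simulate_cv2_counts(
    n_genes: int,
    n_cells: int,
    a0: float = 0.25,
    a1: float = 4.0,
    mean_log: float = 2.0,
    mean_sd: float = 1.5,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series]:
    """Null expression whose gene-wise CV² follows a1/μ + a0 exactly.

    Raw counts are negative binomial with size 1/a0 and mean μ/a1; the
    returned frame is the a1-scaled (depth-normalized) expression, so that
    in normalized units CV²(x) = a1/μ + a0. Used as the calibration bed
    for the trend fit and the excess-variability test.
    """
    rng = np.random.default_rng(seed)
    mu = rng.lognormal(mean_log, mean_sd, n_genes)  # normalized-unit means
    m = mu / a1
    size = 1.0 / a0
    lam = rng.gamma(shape=size, scale=m[:, None] / size, size=(n_genes, n_cells))
    counts = rng.poisson(lam)
    width = len(str(n_genes))
    genes = pd.Index([f"g{i + 1:0{width}d}" for i in range(n_genes)], name="gene")
    cells = [f"c{j + 1:04d}" for j in range(n_cells)]
    expr = pd.DataFrame(a1 * counts.astype(float), index=genes, columns=cells)
    return expr, pd.Series(mu, index=genes, name="true_mu")
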