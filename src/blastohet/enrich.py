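"""Gene-set over-representation with a multi-cutoff consensus rule.

Over-representation of a gene list in user-supplied GMT collections is
tested per set with a one-sided Fisher exact test inside an explicit
universe, BH-adjusted across sets. The consensus rule regenerates the DE
gene list under six (FDR, |log2 FC|) cutoff pairs and calls a set
consensus-enriched only when it is significant (p < alpha) at every
cutoff — a conservative open surrogate for proprietary pathway platforms.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats

from .de import bh_adjust

logger = logging.getLogger(__name__)

DEFAULT_CUTOFFS: tuple[tuple[float, float], ...] = (
    (0.05, 0.5),
    (0.05, 1.0),
    (0.1, 0.5),
    (0.1, 1.0),
    (0.2, 0.5),
    (0.2, 1.0),
)


@dataclass
class GeneSetCollection:
    sets: dict[str, set]
    descriptions: dict[str, str] = field(default_factory=dict)
    source: str = ""

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise ValueError(f"gene set {name!r} is empty")


def read_gmt(path) -> GeneSetCollection:
    """Parse a GMT file (name TAB description TAB genes...).

    Duplicate genes within a set are deduplicated with a warning; malformed
    lines and duplicate set names raise with the line number.
    """
    sets: dict[str, set] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: malformed GMT line (need >= 3 fields)")
            name, desc, *genes = fields
            genes = [g for g in genes if g]
            if not genes:
                raise ValueError(f"{path}:{lineno}: gene set {name!r} has no genes")
            if name in sets:
                raise ValueError(f"{path}:{lineno}: duplicate set name {name!r}")
            if len(set(genes)) < len(genes):
                logger.warning("%s:%d: duplicate genes in set %r deduplicated", path, lineno, name)
            sets[name] = set(genes)
            descriptions[name] = desc
    return GeneSetCollection(sets=sets, descriptions=descriptions, source=str(path))


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name, members in collection.sets.items():
            desc = collection.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *sorted(members)]) + "\n")


def overrepresentation(genes, universe, collection: GeneSetCollection) -> pd.DataFrame:
    """One-sided Fisher exact over-representation of ``genes`` per set.

    Set membership is intersected with the universe before testing. An
    empty gene list yields p = 1 everywhere.
    """
    universe = set(universe)
    genes = set(genes)
    if not genes <= universe:
        raise ValueError("gene list must be a subset of the universe")
    N = len(universe)
    n = len(genes)
    rows = []
    for name, members in collection.sets.items():
        members_u = members & universe
        K = len(members_u)
        k = len(genes & members_u)
        if n == 0 or K == 0:
            p = 1.0
        else:
            table = [[k, n - k], [K - k, N - n - (K - k)]]
            p = float(scipy.stats.fisher_exact(table, alternative="greater")[1])
        rows.append((name, k, K, n, N, p))
    out = pd.DataFrame(
        rows, columns=["set", "overlap", "set_size", "list_size", "universe_size", "p"]
    ).set_index("set")
    out["fdr"] = bh_adjust(out["p"].to_numpy()) if len(out) else []
    return out


def consensus_enrichment(
    de: pd.DataFrame,
    collection: GeneSetCollection,
    cutoffs=DEFAULT_CUTOFFS,
    alpha: float = 0.05,
    universe=None,
) -> pd.DataFrame:
    """Per-set consensus enrichment across six (FDR, |lfc|) cutoff pairs.

    ``de`` is a differential-expression table (index = genes, columns
    include ``fdr`` and ``lfc``). A set is consensus-enriched iff its
    Fisher p < alpha at every cutoff. A cutoff yielding an empty DE list
    marks all sets non-hit there (logged).
    """
    cutoffs = list(cutoffs)
    if len(cutoffs) != 6:
        raise ValueError("the consensus rule takes exactly six cutoff pairs")
    universe = set(de.index) if universe is None else set(universe)
    hit_cols = {}
    p_cols = {}
    for fdr_cut, lfc_cut in cutoffs:
        key = f"fdr{fdr_cut}_lfc{lfc_cut}"
        de_genes = set(de.index[(de["fdr"] < fdr_cut) & (de["lfc"].abs() >= lfc_cut)])
        de_genes &= universe
        if not de_genes:
            logger.info("cutoff %s: empty DE list; all sets non-hit", key)
            hit_cols[key] = pd.Series(False, index=list(collection.sets))
            p_cols[key] = pd.Series(1.0, index=list(collection.sets))
            continue
        res = overrepresentation(de_genes, universe, collection)
        hit_cols[key] = res["p"] < alpha
        p_cols[key] = res["p"]
    out = pd.DataFrame({f"hit_{k}": v for k, v in hit_cols.items()})
    for k, v in p_cols.items():
        out[f"p_{k}"] = v
    out["consensus"] = out[[c for c in out.columns if c.startswith("hit_")]].all(axis=1)
    out.index.name = "set"
    return out
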