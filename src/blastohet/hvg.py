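"""Variable-gene detection from the mean-CV² overdispersion trend.

For single-cell counts the squared coefficient of variation of a gene is
well described as a function of its mean after depth normalization,

    CV² = a₁/μ + a₀ ,

where the a₁/μ term is the Poisson-like sampling component and a₀ the
asymptotic biological overdispersion. The trend is fitted by a gamma-family
GLM with identity link on 1/μ over genes above a mean floor; each gene is
then tested for excess variability with the chi-square ratio statistic

    (n − 1) · CV²_obs / CV²_trend(μ)  ~  χ²(n − 1)   (upper tail),

followed by Benjamini–Hochberg adjustment. Genes at FDR < 0.1 (default)
are called variable.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm

from .matrix import ExpressionMatrix, NormalizedMatrix

logger = logging.getLogger(__name__)


def _as_expression_frame(data, basis: str) -> pd.DataFrame:
    """Coerce input to a genes x cells frame of normalized expression."""
    if isinstance(data, pd.DataFrame):
        return data
    if isinstance(data, NormalizedMatrix):
        return data.tpm
    if isinstance(data, ExpressionMatrix):
        if basis == "sizefactor":
            from .trajectory import estimate_size_factors

            sf = estimate_size_factors(data.counts)
            return data.counts / sf
        raise ValueError("pass a NormalizedMatrix for TPM-basis moments")
    raise TypeError(f"unsupported expression container: {type(data)!r}")


def gene_moments(data, cells=None, basis: str = "sizefactor") -> pd.DataFrame:
    """Per-gene mean and CV² over the given cells.

    ``data`` may be a genes x cells DataFrame of already-normalized
    expression, a :class:`NormalizedMatrix` (TPM basis) or an
    :class:`ExpressionMatrix` (size-factor basis, the default reading of
    "normalization with the count number"). CV² is left NaN where μ = 0.
    """
    expr = _as_expression_frame(data, basis)
    if cells is not None:
        expr = expr[pd.Index(cells)]
    n = expr.shape[1]
    if n < 3:
        raise ValueError("need at least 3 cells for gene moments")
    x = expr.to_numpy(dtype=float)
    mu = x.mean(axis=1)
    var = x.var(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv2 = np.where(mu > 0, var / mu**2, np.nan)
    return pd.DataFrame({"mu": mu, "cv2": cv2, "n_cells": n}, index=expr.index)


@dataclass
class FitCoefficients:
    """Fitted CV² = a1/μ + a0 trend."""

    a0: float
    a1: float
    fit_gene_set: pd.Index
    mean_floor: float
    method: str = "gamma_glm"

    def trend(self, mu) -> np.ndarray:
        with np.errstate(divide="ignore"):
            return self.a1 / np.asarray(mu, dtype=float) + self.a0


def _glm_fit(mu: np.ndarray, cv2: np.ndarray) -> tuple[float, float]:
    X = sm.add_constant(1.0 / mu)
    # OLS start keeps the identity-link gamma IRLS in the positive region
    ols = np.linalg.lstsq(X, cv2, rcond=None)[0]
    start = np.clip(ols, 1e-8, None)
    with warnings.catch_warnings():
        # identity link on Gamma is deliberate (positivity checked after fit)
        warnings.simplefilter("ignore")
        model = sm.GLM(cv2, X, family=sm.families.Gamma(link=sm.families.links.Identity()))
    try:
        res = model.fit(start_params=start, maxiter=200)
        a0, a1 = float(res.params[0]), float(res.params[1])
    except Exception:  # singular / non-convergent: fall back to the OLS line
        a0, a1 = float(ols[0]), float(ols[1])
    return a0, a1


def fit_cv2_trend(
    moments: pd.DataFrame,
    min_mean_quantile: float = 0.25,
    method: str = "gamma_glm",
) -> FitCoefficients:
    """Fit CV² = a1/μ + a0 over genes above a mean-quantile floor.

    The gamma GLM (identity link) is robust to the heavy right tail of
    sample CV²; ``method='ols'`` selects a plain least-squares fit. If the
    fitted trend is non-positive anywhere over the fitted mean range the
    floor is raised and the fit retried.
    """
    ok = moments.dropna(subset=["cv2"])
    ok = ok[(ok["mu"] > 0) & (ok["cv2"] > 0)]
    if len(ok) < 10:
        raise ValueError("need >= 10 genes with positive mean and CV² to fit the trend")
    quantile = float(min_mean_quantile)
    for _attempt in range(4):
        floor = float(ok["mu"].quantile(quantile))
        fit_set = ok[ok["mu"] >= floor]
        if len(fit_set) < 10:
            raise ValueError("fewer than 10 genes above the mean floor")
        mu = fit_set["mu"].to_numpy()
        cv2 = fit_set["cv2"].to_numpy()
        if method == "gamma_glm":
            a0, a1 = _glm_fit(mu, cv2)
        elif method == "ols":
            X = sm.add_constant(1.0 / mu)
            beta = np.linalg.lstsq(X, cv2, rcond=None)[0]
            a0, a1 = float(beta[0]), float(beta[1])
        else:
            raise ValueError("method must be 'gamma_glm' or 'ols'")
        trend_lo = a1 / mu.max() + a0
        trend_hi = a1 / mu.min() + a0
        if trend_lo > 0 and trend_hi > 0:
            return FitCoefficients(
                a0=a0, a1=a1, fit_gene_set=fit_set.index, mean_floor=floor, method=method
            )
        quantile = min(quantile + 0.15, 0.9)
        logger.warning("non-positive fitted trend; raising mean floor to q=%.2f", quantile)
    raise ValueError("could not obtain a positive fitted trend")


def call_variable_genes(
    moments: pd.DataFrame, fit: FitCoefficients, fdr_threshold: float = 0.1
) -> pd.DataFrame:
    """Chi-square excess-variability test against the fitted trend.

    Returns the per-gene table (μ, CV², trend CV², ratio, p, FDR,
    is_variable). Genes with μ = 0 are untestable and carry NaN.
    """
    from .de import bh_adjust

    n = int(moments["n_cells"].iloc[0])
    if n < 3:
        raise ValueError("need at least 3 cells")
    out = moments.copy()
    out["trend_cv2"] = fit.trend(out["mu"])
    out["ratio"] = out["cv2"] / out["trend_cv2"]
    testable = out["cv2"].notna() & (out["trend_cv2"] > 0)
    stat = (n - 1) * out.loc[testable, "ratio"]
    p = scipy.stats.chi2.sf(stat, df=n - 1)
    out["p"] = np.nan
    out.loc[testable, "p"] = p
    out["fdr"] = np.nan
    out.loc[testable, "fdr"] = bh_adjust(p)
    out["is_variable"] = out["fdr"] < fdr_threshold
    return out


def compare_hvg_counts(
    tables: dict[str, pd.DataFrame], reference: str
) -> pd.DataFrame:
    """Variable-gene counts per group with two-proportion z-tests vs reference.

    All tables must share the same gene universe (same index)."""
    from statsmodels.stats.proportion import proportions_ztest

    if reference not in tables:
        raise ValueError(f"reference group {reference!r} not among tables")
    ref_index = tables[reference].index
    for name, tab in tables.items():
        if not tab.index.equals(ref_index):
            raise ValueError(f"gene universe of {name!r} differs from {reference!r}")
    n_genes = len(ref_index)
    ref_count = int(tables[reference]["is_variable"].sum())
    rows = []
    for name, tab in tables.items():
        count = int(tab["is_variable"].sum())
        if name == reference:
            rows.append((name, count, n_genes, np.nan, np.nan, "reference"))
            continue
        if count == 0 and ref_count == 0:
            rows.append((name, count, n_genes, np.nan, np.nan, "skipped: both empty"))
            continue
        z, p = proportions_ztest([count, ref_count], [n_genes, n_genes])
        rows.append((name, count, n_genes, float(z), float(p), ""))
    return pd.DataFrame(
        rows, columns=["group", "n_variable", "n_genes", "z", "p", "note"]
    ).set_index("group")
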