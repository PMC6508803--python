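"""Negative-binomial differential-expression engine.

A deliberately compact NB pipeline for replicated count matrices:
median-of-ratios size factors, a low-expression pre-filter based on the
overall normalized mean, method-of-moments dispersion estimation with a
1/mu trend and log-scale shrinkage, per-genotype NB Wald contrasts
(stress vs control) fitted by IRLS, and Benjamini–Hochberg correction.

The model for gene g in sample j is

    K_gj ~ NB(mean = s_j * q_gj,  Var = mean + alpha_g * mean^2)
    log q_gj = beta_0 + beta_1 * x_j          (x_j = 1 under stress)

and the reported log2 fold-change is beta_1 / ln 2 with its Wald standard
error from the observed Fisher information.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

ALPHA_FLOOR = 1e-8

RESULT_COLUMNS = ["baseMean", "log2FC", "lfcSE", "stat", "pvalue", "padj"]


def _validate_counts(counts: pd.DataFrame) -> None:
    if counts.empty:
        raise ValueError("empty count matrix")
    if counts.index.duplicated().any():
        raise ValueError("duplicate gene ids")
    if counts.columns.duplicated().any():
        raise ValueError("duplicate sample ids")
    values = counts.to_numpy()
    if (values < 0).any():
        raise ValueError("counts must be non-negative")
    if not np.allclose(values, np.round(values)):
        raise ValueError("counts must be integral")


def estimate_size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios depth factors.

    s_j = median over reference genes of K_gj / geomean_g, where the
    reference genes are those with strictly positive counts in every sample.
    """
    _validate_counts(counts)
    values = counts.to_numpy(dtype=float)
    reference = (values > 0).all(axis=1)
    if not reference.any():
        raise ValueError("no gene has nonzero counts in every sample")
    ref = values[reference]
    log_geomean = np.log(ref).mean(axis=1)
    s = np.exp(np.median(np.log(ref) - log_geomean[:, None], axis=0))
    return pd.Series(s, index=counts.columns, name="size_factor")


def normalize_counts(counts: pd.DataFrame, size_factors: pd.Series) -> pd.DataFrame:
    return counts / size_factors.reindex(counts.columns)


@dataclass
class PrefilterResult:
    filtered: pd.DataFrame
    threshold: float
    retained: list[str]
    removed: list[str]


def prefilter_low_expression(
    counts: pd.DataFrame, size_factors: pd.Series
) -> PrefilterResult:
    """Remove genes whose total raw count falls below the adaptive threshold
    T = (overall mean of normalized counts) / (number of samples); the
    comparison is inclusive, so genes with total exactly T are retained."""
    _validate_counts(counts)
    norm = normalize_counts(counts, size_factors)
    threshold = float(norm.to_numpy().mean()) / counts.shape[1]
    totals = counts.sum(axis=1)
    keep = totals >= threshold
    result = PrefilterResult(
        filtered=counts.loc[keep],
        threshold=threshold,
        retained=list(counts.index[keep]),
        removed=list(counts.index[~keep]),
    )
    logger.info(
        "pre-filter: threshold %.3f, retained %d / %d genes",
        threshold, keep.sum(), len(keep),
    )
    return result


# ---------------------------------------------------------------------------
# dispersion estimation
# ---------------------------------------------------------------------------

@dataclass
class DispersionEstimates:
    """Gene-wise, trended, and final (shrunken) dispersions, indexed by gene."""

    genewise: pd.Series
    trend: pd.Series
    final: pd.Series
    trend_coef: tuple[float, float] = (0.0, 0.0)  # (a0, a1) of a0 + a1/mu


def _design_cells(design: pd.DataFrame) -> list[np.ndarray]:
    """Column index arrays of the (genotype, treatment) replicate groups."""
    cells = []
    for _, grp in design.groupby(["genotype", "treatment"], sort=False):
        cells.append(np.asarray([design.index.get_loc(s) for s in grp.index]))
    return cells


def estimate_dispersions(
    counts: pd.DataFrame,
    size_factors: pd.Series,
    design: pd.DataFrame,
    shrink_weight: float = 0.5,
) -> DispersionEstimates:
    """Method-of-moments dispersions pooled across replicate cells.

    Within each design cell with >= 2 replicates, alpha is estimated from
    normalized counts as (var - mean) / mean^2; cell estimates are pooled
    with (n_c - 1) weights and clipped at zero.  A hyperbolic trend
    alpha_tr(mu) = a0 + a1/mu is least-squares fitted to positive gene-wise
    values, and the final dispersion is a log-scale weighted average of
    gene-wise and trend values (weight ``shrink_weight`` on the gene-wise
    component), floored at 1e-8.
    """
    if not 0 <= shrink_weight <= 1:
        raise ValueError("shrink_weight must be in [0, 1]")
    norm = normalize_counts(counts, size_factors).to_numpy()
    cells = [c for c in _design_cells(design) if len(c) >= 2]
    if not cells:
        raise ValueError("need >= 2 replicates in at least one design cell")

    num = np.zeros(norm.shape[0])
    den = np.zeros(norm.shape[0])
    for cell in cells:
        block = norm[:, cell]
        m = block.mean(axis=1)
        v = block.var(axis=1, ddof=1)
        w = len(cell) - 1
        with np.errstate(divide="ignore", invalid="ignore"):
            a_cell = np.where(m > 0, (v - m) / np.where(m > 0, m, 1.0) ** 2, 0.0)
        num += w * a_cell
        den += w
    genewise = np.maximum(num / den, 0.0)

    mu_bar = norm.mean(axis=1)
    use = (genewise > 0) & (mu_bar > 0)
    if use.sum() >= 2:
        X = np.column_stack([np.ones(use.sum()), 1.0 / mu_bar[use]])
        coef, *_ = np.linalg.lstsq(X, genewise[use], rcond=None)
        a0, a1 = float(coef[0]), float(coef[1])
    else:  # degenerate: no overdispersion signal anywhere
        a0, a1 = 0.0, 0.0
    with np.errstate(divide="ignore"):
        trend = np.where(mu_bar > 0, a0 + a1 / np.where(mu_bar > 0, mu_bar, 1.0), a0)
    trend = np.maximum(trend, ALPHA_FLOOR)

    final = np.exp(
        shrink_weight * np.log(np.maximum(genewise, ALPHA_FLOOR))
        + (1 - shrink_weight) * np.log(trend)
    )
    final = np.maximum(final, ALPHA_FLOOR)
    idx = counts.index
    return DispersionEstimates(
        genewise=pd.Series(genewise, index=idx, name="genewise"),
        trend=pd.Series(trend, index=idx, name="trend"),
        final=pd.Series(final, index=idx, name="final"),
        trend_coef=(a0, a1),
    )


# ---------------------------------------------------------------------------
# Wald contrasts
# ---------------------------------------------------------------------------

def nb_wald_contrast(
    counts: pd.DataFrame,
    size_factors: pd.Series,
    dispersions: DispersionEstimates,
    design: pd.DataFrame,
    genotype: str,
) -> pd.DataFrame:
    """Stress-vs-control NB Wald test within one genotype's samples.

    Returns a DataFrame with columns baseMean, log2FC, lfcSE, stat, pvalue,
    padj.  Genes with all-zero counts among the contrast samples, and genes
    whose IRLS fit fails, carry NaN statistics and are excluded from the BH
    denominator.
    """
    sub = design[design["genotype"] == genotype]
    if sub.empty:
        raise ValueError(f"genotype {genotype!r} not present in the design")
    if set(sub["treatment"]) != {"control", "stress"}:
        raise ValueError(f"genotype {genotype!r} lacks both treatments")
    samples = list(sub.index)
    y_all = counts[samples].to_numpy(dtype=float)
    x = (sub["treatment"] == "stress").to_numpy(dtype=float)
    X = np.column_stack([np.ones_like(x), x])
    offset = np.log(size_factors.reindex(samples).to_numpy())
    alpha = dispersions.final.reindex(counts.index).to_numpy()

    base_mean = normalize_counts(counts, size_factors).mean(axis=1).to_numpy()
    ln2 = np.log(2.0)
    n_genes = counts.shape[0]
    log2fc = np.full(n_genes, np.nan)
    lfc_se = np.full(n_genes, np.nan)

    for i in range(n_genes):
        y = y_all[i]
        if y.sum() == 0:
            continue
        try:
            model = sm.GLM(
                y, X,
                family=sm.families.NegativeBinomial(alpha=max(alpha[i], ALPHA_FLOOR)),
                offset=offset,
            )
            fit = model.fit(maxiter=100, tol=1e-8)
            if not np.all(np.isfinite(fit.params)) or not np.all(np.isfinite(fit.bse)):
                raise ValueError("non-finite estimates")
        except Exception as exc:  # non-convergence is flagged, never silent
            logger.warning("gene %s: NB fit failed (%s)", counts.index[i], exc)
            continue
        log2fc[i] = fit.params[1] / ln2
        lfc_se[i] = fit.bse[1] / ln2

    stat = log2fc / lfc_se
    pvalue = 2.0 * scipy.stats.norm.sf(np.abs(stat))
    padj = bh_adjust(pvalue)
    return pd.DataFrame(
        {
            "baseMean": base_mean,
            "log2FC": log2fc,
            "lfcSE": lfc_se,
            "stat": stat,
            "pvalue": pvalue,
            "padj": padj,
        },
        index=counts.index,
    )


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, order-preserving.

    NaN entries are excluded from the ranking (and from the denominator m)
    and stay NaN in the output.
    """
    p = np.asarray(pvalues, dtype=float)
    out = np.full(p.shape, np.nan)
    mask = ~np.isnan(p)
    if ((p[mask] < 0) | (p[mask] > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    if mask.any():
        out[mask] = multipletests(p[mask], method="fdr_bh")[1]
    return out
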