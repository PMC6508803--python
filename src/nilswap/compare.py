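"""Downstream comparative analyses for the reciprocal allele-swap design.

Given per-genotype stress-vs-control contrast results, this module calls DE
gene sets, classifies genes by their allele-responsiveness ratio (how much
more a gene responds to stress under the resistant-parent allele than under
the sensitive-parent allele), summarizes set overlaps, compares fold-change
magnitudes between gene sets, computes a variance-ranked PCA of transformed
counts, and evaluates the relative-root-growth (RRG) resistance phenotype.

The ratio classification operates on the linear fold-change scale: a gene
passes a fold threshold f iff log2FC_ref - log2FC_alt >= log2(f).  The
comparison is inclusive at the boundary (a difference of exactly 1.0 passes
f = 2), with a tiny absolute slack so that values equal at printed precision
are not rejected for binary round-off.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.stats

_BOUNDARY_TOL = 1e-9


@dataclass
class DECriteria:
    """Thresholds for calling a gene differentially expressed."""

    min_abs_log2fc: float = 1.0
    max_padj: float = 0.05
    min_count_one_sample: float = 8.0  # on the normalized-count scale

    def __post_init__(self):
        if self.min_abs_log2fc <= 0 or self.max_padj <= 0 or self.min_count_one_sample <= 0:
            raise ValueError("DE criteria thresholds must be positive")


@dataclass
class DEGeneSet:
    genotype: str
    direction: str  # "up" or "down"
    genes: list[str]
    criteria: DECriteria

    def __len__(self) -> int:
        return len(self.genes)


def call_de_genes(
    result: pd.DataFrame,
    norm_counts: pd.DataFrame,
    criteria: DECriteria = DECriteria(),
    genotype: str = "",
) -> tuple[DEGeneSet, DEGeneSet]:
    """Call up- and down-regulated genes from a contrast result.

    A gene is up iff log2FC >= min_abs_log2fc, padj <= max_padj, and its
    normalized count reaches min_count_one_sample in at least one sample;
    down is symmetric with log2FC <= -min_abs_log2fc.
    """
    if "padj" not in result.columns:
        raise ValueError("contrast result lacks a padj column")
    missing = result.index.difference(norm_counts.index)
    if len(missing):
        raise ValueError(f"normalized counts missing for {len(missing)} tested genes")
    max_norm = norm_counts.reindex(result.index).max(axis=1)
    expressed = max_norm >= criteria.min_count_one_sample
    significant = result["padj"] <= criteria.max_padj
    up = result["log2FC"] >= criteria.min_abs_log2fc
    down = result["log2FC"] <= -criteria.min_abs_log2fc
    up_set = DEGeneSet(genotype, "up", list(result.index[up & significant & expressed]), criteria)
    down_set = DEGeneSet(genotype, "down", list(result.index[down & significant & expressed]), criteria)
    return up_set, down_set


# ---------------------------------------------------------------------------
# allele-responsiveness ratio
# ---------------------------------------------------------------------------

def ratio_classify(lfc_ref: float, lfc_alt: float, fold_threshold: float) -> bool:
    """Does the linear fold-change ratio between the resistant-allele and
    sensitive-allele responses reach ``fold_threshold``?  Inclusive."""
    if fold_threshold <= 1:
        raise ValueError("fold_threshold must exceed 1")
    if not (np.isfinite(lfc_ref) and np.isfinite(lfc_alt)):
        raise ValueError("log2 fold-changes must be finite")
    return bool((lfc_ref - lfc_alt) >= np.log2(fold_threshold) - _BOUNDARY_TOL)


def classify_table(
    rows: Iterable[tuple[str, float, float]],
    thresholds: Sequence[float] = (1.5, 2.0),
) -> tuple[pd.DataFrame, dict[float, int]]:
    """Build the allele-comparison table, sorted by descending delta.

    Each input row is (gene, log2FC under the resistant allele, log2FC under
    the sensitive allele).  Returns the table (columns gene, lfc_ref,
    lfc_alt, delta, ratio_class) and the per-threshold pass counts.
    """
    thresholds = sorted(thresholds)
    records = []
    for gene, lfc_ref, lfc_alt in rows:
        delta = lfc_ref - lfc_alt
        passed = [t for t in thresholds if ratio_classify(lfc_ref, lfc_alt, t)]
        label = f">={max(passed)}x" if passed else f"<{thresholds[0]}x"
        records.append((gene, lfc_ref, lfc_alt, delta, label))
    table = pd.DataFrame(
        records, columns=["gene", "lfc_ref", "lfc_alt", "delta", "ratio_class"]
    ).sort_values("delta", ascending=False, kind="mergesort").reset_index(drop=True)
    counts = {
        t: int(sum(ratio_classify(r, a, t) for _, r, a in
                   zip(table["gene"], table["lfc_ref"], table["lfc_alt"])))
        for t in thresholds
    }
    return table, counts


@dataclass
class VennSummary:
    only_a: int
    shared: int
    only_b: int


def venn_counts(set_a: Iterable[str], set_b: Iterable[str]) -> VennSummary:
    a, b = set(set_a), set(set_b)
    return VennSummary(only_a=len(a - b), shared=len(a & b), only_b=len(b - a))


# ---------------------------------------------------------------------------
# transform + PCA
# ---------------------------------------------------------------------------

def transform_counts(counts: pd.DataFrame, size_factors: pd.Series) -> pd.DataFrame:
    """Depth-normalized shifted-log transform: log2(K/s + 1)."""
    if (size_factors <= 0).any():
        raise ValueError("size factors must be positive")
    return np.log2(counts / size_factors.reindex(counts.columns) + 1.0)


@dataclass
class PCAResult:
    scores: pd.DataFrame            # samples x components
    variance_ratio: np.ndarray      # per component, sums to 1
    genes_used: list[str]


def pca_top_variance(transformed: pd.DataFrame, n_top: int = 500) -> PCAResult:
    """PCA of the n_top highest-variance genes.

    Genes are ranked by row variance across samples; rows are centered (not
    scaled) and sample scores come from the SVD of the samples x genes
    matrix.
    """
    if transformed.shape[1] < 2:
        raise ValueError("PCA needs at least 2 samples")
    if n_top > transformed.shape[0]:
        raise ValueError("n_top exceeds the number of genes")
    row_var = transformed.var(axis=1, ddof=1)
    top = row_var.sort_values(ascending=False, kind="mergesort").index[:n_top]
    X = transformed.loc[top].to_numpy().T          # samples x genes
    X = X - X.mean(axis=0, keepdims=True)
    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    scores = U * S
    var = S**2
    ratio = var / var.sum() if var.sum() > 0 else np.zeros_like(var)
    cols = [f"PC{i + 1}" for i in range(scores.shape[1])]
    return PCAResult(
        scores=pd.DataFrame(scores, index=transformed.columns, columns=cols),
        variance_ratio=ratio,
        genes_used=list(top),
    )


# ---------------------------------------------------------------------------
# magnitude comparison and phenotype arithmetic
# ---------------------------------------------------------------------------

def magnitude_test(
    lfc_set_a: Sequence[float],
    lfc_set_b: Sequence[float],
    method: str = "welch",
) -> tuple[float, float]:
    """Compare fold-change magnitudes of two gene sets.

    Default is Welch's two-sample t on the log2FC values; ``method="mannwhitney"``
    switches to the two-sided Mann–Whitney U.  Degenerate identical
    zero-variance inputs return (0.0, 1.0).
    """
    a = np.asarray(lfc_set_a, dtype=float)
    b = np.asarray(lfc_set_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each set needs at least 2 values")
    if method == "welch":
        stat, p = scipy.stats.ttest_ind(a, b, equal_var=False)
    elif method == "mannwhitney":
        stat, p = scipy.stats.mannwhitneyu(a, b, alternative="two-sided")
    else:
        raise ValueError(f"unknown method {method!r}")
    if np.isnan(stat):  # both sets constant and equal
        return 0.0, 1.0
    return float(stat), float(p)


def rrg(trg_stress: float, trg_control: float) -> float:
    """Relative root growth: stress total root growth over control."""
    if trg_control <= 0:
        raise ValueError("control total root growth must be positive")
    return trg_stress / trg_control
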