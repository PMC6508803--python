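"""Shared fixtures: simulated experiments reused across test modules.

The heavier simulations (the 10,000-gene null and the default planted-class
experiment) are session-scoped so the NB fits run once.
"""

import numpy as np
import pandas as pd
import pytest

from nilswap import de, simulate


def bh_oracle(pvals):
    """Naive O(m^2) step-up: adj_i = min over ranks above i of m*p/rank."""
    p = list(pvals)
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adj = [None] * m
    running_min = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        running_min = min(running_min, m * p[i] / rank_from_top)
        adj[i] = min(running_min, 1.0)
    return adj


NULL_FRACTIONS = {
    "null": 1.0,
    "allele_dependent": 0.0,
    "allele_independent": 0.0,
    "background_specific": 0.0,
    "introgression_effect": 0.0,
}


def run_null_contrast(n_genes: int, seed: int) -> pd.DataFrame:
    """Simulate an all-null experiment and test one genotype's contrast with
    the true (known) dispersions, mirroring the calibration study design."""
    cfg = simulate.SimConfig(n_genes=n_genes, seed=seed, class_fractions=NULL_FRACTIONS)
    counts, design, truth = simulate.simulate_counts(cfg)
    sf = de.estimate_size_factors(counts)
    filtered = de.prefilter_low_expression(counts, sf).filtered
    alpha = truth.table["alpha"]
    known = de.DispersionEstimates(
        genewise=alpha, trend=alpha, final=alpha.reindex(filtered.index)
    )
    return de.nb_wald_contrast(filtered, sf, known, design, "parentA")


@pytest.fixture(scope="session")
def null_contrast_10k() -> pd.DataFrame:
    """Wald results for 10,000 null genes, dispersions known."""
    return run_null_contrast(10_000, seed=20240917)


def run_recovery_contrast(
    n_genes: int = 1000,
    mu: float = 200.0,
    alpha: float = 0.05,
    lfc: float = 2.0,
    n_rep: int = 4,
    seed: int = 42,
) -> pd.DataFrame:
    """Planted single-effect experiment: lfc log2 units, known dispersion."""
    rng = np.random.default_rng(seed)
    mean = np.concatenate([np.full(n_rep, mu), np.full(n_rep, mu * 2.0**lfc)])
    counts = simulate.sample_nb(
        rng, np.tile(mean, (n_genes, 1)), np.full((n_genes, 2 * n_rep), alpha)
    )
    counts = pd.DataFrame(
        counts,
        index=[f"g{i}" for i in range(n_genes)],
        columns=[f"s{j}" for j in range(2 * n_rep)],
    )
    design = pd.DataFrame(
        {
            "genotype": "parentA",
            "treatment": ["control"] * n_rep + ["stress"] * n_rep,
            "replicate": list(range(1, n_rep + 1)) * 2,
        },
        index=counts.columns,
    )
    sf = pd.Series(1.0, index=counts.columns)
    known = pd.Series(alpha, index=counts.index)
    disp = de.DispersionEstimates(genewise=known, trend=known, final=known)
    return de.nb_wald_contrast(counts, sf, disp, design, "parentA")


@pytest.fixture(scope="session")
def recovery_contrast() -> pd.DataFrame:
    """1,000 genes with a planted log2FC of 2 at mu=200, alpha=0.05."""
    return run_recovery_contrast()


@pytest.fixture(scope="session")
def default_experiment():
    """A 2,000-gene experiment with the default planted-class mixture, run
    through the full DE pipeline for all four genotypes."""
    cfg = simulate.SimConfig(n_genes=2000, seed=7)
    counts, design, truth = simulate.simulate_counts(cfg)
    sf = de.estimate_size_factors(counts)
    filtered = de.prefilter_low_expression(counts, sf).filtered
    disp = de.estimate_dispersions(filtered, sf, design)
    norm = de.normalize_counts(filtered, sf)
    results = {
        g: de.nb_wald_contrast(filtered, sf, disp, design, g)
        for g in simulate.GENOTYPES
    }
    return {
        "counts": counts,
        "design": design,
        "truth": truth,
        "size_factors": sf,
        "filtered": filtered,
        "norm": norm,
        "results": results,
    }
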