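"""Tests for the NB differential-expression engine."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats
from hypothesis import given, settings, strategies as st

from conftest import bh_oracle

from nilswap import de, simulate
from nilswap.de import (
    bh_adjust,
    estimate_dispersions,
    estimate_size_factors,
    nb_wald_contrast,
    prefilter_low_expression,
)


def _frame(rows, genes=None, samples=None):
    rows = np.asarray(rows)
    genes = genes or [f"g{i}" for i in range(rows.shape[0])]
    samples = samples or [f"s{j}" for j in range(rows.shape[1])]
    return pd.DataFrame(rows, index=genes, columns=samples)


class TestSizeFactors:
    def test_identical_samples(self):
        counts = _frame([[5, 5], [10, 10], [3, 3]])
        assert estimate_size_factors(counts).tolist() == pytest.approx([1.0, 1.0])

    def test_scaling_equivariance(self):
        counts = _frame([[5, 10], [10, 20], [3, 6]])
        s = estimate_size_factors(counts)
        assert s["s1"] / s["s0"] == pytest.approx(2.0)

    def test_toy_matrix_matches_hand_oracle(self):
        """[[2,4],[8,16],[2,8]]: geometric means (2.828, 11.31, 4) give
        per-sample ratio medians 1/sqrt(2) and sqrt(2)."""
        counts = _frame([[2, 4], [8, 16], [2, 8]])
        s = estimate_size_factors(counts)
        assert s.to_numpy() == pytest.approx([2**-0.5, 2**0.5])

    def test_reference_genes_exclude_zeros(self):
        # the gene with a zero is not part of the reference set
        counts = _frame([[2, 4], [8, 16], [0, 100]])
        s = estimate_size_factors(counts)
        assert s.to_numpy() == pytest.approx([2**-0.5, 2**0.5])

    def test_sample_permutation_permutes_factors(self):
        counts = _frame(np.random.default_rng(0).poisson(50, (30, 4)))
        s = estimate_size_factors(counts)
        perm = ["s2", "s0", "s3", "s1"]
        s_perm = estimate_size_factors(counts[perm])
        assert s_perm.tolist() == pytest.approx(s[perm].tolist())

    def test_error_when_no_reference_gene(self):
        with pytest.raises(ValueError):
            estimate_size_factors(_frame([[0, 5], [5, 0]]))


class TestPrefilter:
    def test_toy_threshold(self):
        """T = (206/8)/2 = 12.875; only the (100,100) gene survives."""
        counts = _frame([[0, 0], [1, 1], [100, 100], [3, 1]])
        sf = pd.Series([1.0, 1.0], index=counts.columns)
        res = prefilter_low_expression(counts, sf)
        assert res.threshold == pytest.approx(12.875)
        assert res.retained == ["g2"]
        assert set(res.removed) == {"g0", "g1", "g3"}

    def test_all_zero_gene_removed(self):
        counts = _frame([[0, 0], [50, 60]])
        sf = pd.Series([1.0, 1.0], index=counts.columns)
        assert "g0" in prefilter_low_expression(counts, sf).removed

    def test_boundary_inclusive_single_gene_single_sample(self):
        counts = _frame([[7]])
        sf = pd.Series([1.0], index=counts.columns)
        res = prefilter_low_expression(counts, sf)
        assert res.threshold == pytest.approx(7.0)
        assert res.retained == ["g0"]

    def test_global_rescale_preserves_relative_normalization(self):
        """Multiplying all counts by c leaves size factors unchanged (the
        median of ratios is scale-free), so every between-sample normalized
        expression ratio is invariant."""
        rng = np.random.default_rng(1)
        counts = _frame(rng.poisson(40, (50, 6)))
        sf = estimate_size_factors(counts)
        sf_scaled = estimate_size_factors(counts * 3)
        assert sf_scaled.to_numpy() == pytest.approx(sf.to_numpy())
        norm = de.normalize_counts(counts, sf)
        norm_scaled = de.normalize_counts(counts * 3, sf_scaled)
        assert norm_scaled.to_numpy() == pytest.approx(3 * norm.to_numpy())


def _one_cell_design(n_rep, columns):
    return pd.DataFrame(
        {"genotype": "g", "treatment": "control", "replicate": range(1, n_rep + 1)},
        index=columns,
    )


class TestDispersions:
    def test_poisson_counts_give_near_zero_dispersion(self):
        rng = np.random.default_rng(0)
        counts = _frame(rng.poisson(200, (400, 40)))
        sf = pd.Series(1.0, index=counts.columns)
        d = estimate_dispersions(counts, sf, _one_cell_design(40, counts.columns))
        assert np.median(d.final) <= 0.01

    def test_nb_dispersion_recovered(self):
        """alpha=0.2 at mu=200 with 50 replicates: the shrunken estimate is
        within 25% of truth for >=90% of genes."""
        rng = np.random.default_rng(5)
        counts = _frame(
            simulate.sample_nb(rng, np.full((1000, 50), 200.0), np.full((1000, 50), 0.2))
        )
        sf = pd.Series(1.0, index=counts.columns)
        d = estimate_dispersions(counts, sf, _one_cell_design(50, counts.columns))
        rel_err = np.abs(d.final - 0.2) / 0.2
        assert (rel_err <= 0.25).mean() >= 0.90

    def test_constant_gene_zero_genewise(self):
        counts = _frame([[10, 10, 10, 10], [5, 9, 14, 2]])
        sf = pd.Series(1.0, index=counts.columns)
        d = estimate_dispersions(counts, sf, _one_cell_design(4, counts.columns))
        assert d.genewise["g0"] == 0.0
        assert d.final["g0"] >= de.ALPHA_FLOOR

    def test_requires_replication(self):
        counts = _frame([[3, 4]])
        sf = pd.Series(1.0, index=counts.columns)
        design = pd.DataFrame(
            {"genotype": ["a", "b"], "treatment": "control", "replicate": 1},
            index=counts.columns,
        )
        with pytest.raises(ValueError):
            estimate_dispersions(counts, sf, design)


def _contrast_inputs(counts):
    n = counts.shape[1] // 2
    design = pd.DataFrame(
        {
            "genotype": "parentA",
            "treatment": ["control"] * n + ["stress"] * n,
            "replicate": list(range(1, n + 1)) * 2,
        },
        index=counts.columns,
    )
    sf = pd.Series(1.0, index=counts.columns)
    alpha = pd.Series(0.05, index=counts.index)
    disp = de.DispersionEstimates(genewise=alpha, trend=alpha, final=alpha)
    return sf, disp, design


class TestWaldContrast:
    def test_identical_groups_give_zero_lfc(self):
        counts = _frame([[40, 60, 40, 60], [7, 7, 7, 7]])
        sf, disp, design = _contrast_inputs(counts)
        res = nb_wald_contrast(counts, sf, disp, design, "parentA")
        assert res["log2FC"].to_numpy() == pytest.approx([0.0, 0.0], abs=1e-6)
        assert res["stat"].to_numpy() == pytest.approx([0.0, 0.0], abs=1e-6)

    def test_all_zero_gene_flagged_na_and_excluded_from_bh(self):
        counts = _frame([[0, 0, 0, 0], [40, 50, 90, 100], [30, 35, 30, 40]])
        sf, disp, design = _contrast_inputs(counts)
        res = nb_wald_contrast(counts, sf, disp, design, "parentA")
        assert res.loc["g0", ["log2FC", "pvalue", "padj"]].isna().all()
        m = res["pvalue"].notna().sum()
        assert m == 2  # BH denominator excludes the untested gene

    def test_lfc_recovery(self, recovery_contrast):
        """Planted log2FC=2 at mu=200, alpha=0.05, 4+4 replicates."""
        mean_lfc = recovery_contrast["log2FC"].mean()
        assert 1.8 <= mean_lfc <= 2.2

    def test_null_pvalues_uniform(self, null_contrast_10k):
        """Wald p-values are approximately uniform under the null."""
        p = null_contrast_10k["pvalue"].dropna()
        assert len(p) > 9000
        assert scipy.stats.kstest(p, "uniform").pvalue > 0.01

    def test_unknown_genotype_or_missing_treatment(self):
        counts = _frame([[5, 6, 7, 8]])
        sf, disp, design = _contrast_inputs(counts)
        with pytest.raises(ValueError):
            nb_wald_contrast(counts, sf, disp, design, "nope")
        one_treatment = design.copy()
        one_treatment["treatment"] = "control"
        with pytest.raises(ValueError):
            nb_wald_contrast(counts, sf, disp, one_treatment, "parentA")


class TestBHAdjust:
    def test_single_value_identity(self):
        assert bh_adjust([0.03]) == pytest.approx([0.03])

    def test_worked_example(self):
        assert bh_adjust([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)

    def test_nan_passthrough(self):
        out = bh_adjust([0.01, np.nan, 0.5])
        assert np.isnan(out[1])
        assert out[[0, 2]] == pytest.approx(bh_adjust([0.01, 0.5]))

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    @settings(derandomize=True, deadline=None, max_examples=50)
    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=40))
    def test_matches_quadratic_oracle(self, pvals):
        assert bh_adjust(pvals) == pytest.approx(bh_oracle(pvals))

    @settings(derandomize=True, deadline=None, max_examples=50)
    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=40))
    def test_sandwich_property(self, pvals):
        adj = bh_adjust(pvals)
        p = np.asarray(pvals)
        assert (adj >= p - 1e-12).all()
        assert (adj <= np.minimum(len(p) * p, 1.0) + 1e-12).all()
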