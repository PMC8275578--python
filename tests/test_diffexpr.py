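"""Differential-expression chain: filter, TMM, dispersion, exact test."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import binomtest

from cpgflex.diffexpr import (
    Contrast,
    _conditional_exact_p,
    build_contrast,
    cpm_filter,
    deg_percentage,
    estimate_dispersion,
    nb_exact_test,
    run_contrast,
    tmm_factors,
)
from cpgflex.simulate import default_design

# Frozen reference: edgeR::calcNormFactors(method="TMM") on the matrix
# regenerated by _tmm_fixture() below.
EDGER_TMM_FACTORS = [1.074132, 1.069917, 1.072441, 0.930677, 0.942120, 0.925366]


def _tmm_fixture():
    rng = np.random.default_rng(7)
    n_genes, n_samples = 200, 6
    base = rng.lognormal(np.log(100), 1.0, n_genes)
    lib_factor = np.array([1.0, 1.5, 0.7, 2.0, 1.2, 0.9])
    counts = np.empty((n_genes, n_samples), dtype=np.int64)
    de = rng.random(n_genes) < 0.10
    fc = np.where(rng.random(n_genes) < 0.5, 4.0, 0.25)
    for j in range(n_samples):
        mean = base * lib_factor[j]
        if j >= 3:
            mean = np.where(de, mean * fc, mean)
        counts[:, j] = rng.poisson(mean)
    return pd.DataFrame(counts, columns=[f"s{j}" for j in range(n_samples)])


class TestCpmFilter:
    def test_hand_computed_keep_set(self):
        counts = pd.DataFrame(
            {
                "s1": [0, 100, 1, 50, 2],
                "s2": [0, 100, 1, 0, 2],
                "s3": [0, 100, 1, 0, 2],
                "s4": [0, 100, 1, 0, 0],
            },
            index=[f"g{i}" for i in range(5)],
        )
        # library sizes: 153, 103, 103, 101 -> any nonzero count clears
        # 1 cpm; g0 is all-zero and g3 is expressed in a single sample
        kept = cpm_filter(counts, min_cpm=1, min_samples=3)
        assert list(kept.index) == ["g1", "g2", "g4"]

    def test_zero_gene_dropped_and_boundary_inclusive(self):
        # lib size 1e6 -> cpm == count; cpm exactly 1.0 in exactly 3 samples kept
        big = pd.DataFrame(
            {f"s{j}": [1, 0] + [0] * 8 + [999989 + j] for j in range(4)},
            index=[f"g{i}" for i in range(11)],
        )
        big.iloc[0, 3] = 0  # gene0: cpm ~1 in exactly 3 samples
        lib = big.sum(0)
        assert ((big.iloc[0] / lib * 1e6) >= 1.0).sum() == 3
        kept = cpm_filter(big, min_cpm=1.0, min_samples=3)
        assert "g0" in kept.index and "g1" not in kept.index

    def test_all_dropped_errors(self):
        counts = pd.DataFrame({"s1": [0, 0], "s2": [1000000, 1000000]})
        with pytest.raises(ValueError):
            cpm_filter(counts, min_cpm=10_000_000, min_samples=1)


class TestTMM:
    def test_identical_samples_unit_factors(self):
        counts = pd.DataFrame({"s1": [10, 20, 30], "s2": [10, 20, 30]})
        assert tmm_factors(counts).to_numpy() == pytest.approx([1, 1], abs=1e-12)

    def test_global_doubling_absorbed_by_library_size(self):
        rng = np.random.default_rng(1)
        a = rng.poisson(50, 300)
        counts = pd.DataFrame({"s1": a, "s2": 2 * a})
        assert tmm_factors(counts).to_numpy() == pytest.approx([1, 1], abs=1e-9)

    def test_matches_edger_reference_within_five_percent(self):
        mine = tmm_factors(_tmm_fixture()).to_numpy()
        assert mine == pytest.approx(EDGER_TMM_FACTORS, rel=0.05)


class TestDispersion:
    def _counts(self, rng, phi, n_genes=2000, n=3, mean=200.0):
        cols = {}
        for j in range(2 * n):
            if phi > 0:
                lam = rng.gamma(1 / phi, mean * phi, n_genes)
            else:
                lam = np.full(n_genes, mean)
            cols[f"s{j}"] = rng.poisson(lam)
        return pd.DataFrame(cols, index=[f"g{i}" for i in range(n_genes)])

    def test_poisson_counts_give_near_zero_common_dispersion(self, rng):
        counts = self._counts(rng, phi=0.0)
        groups = {"a": ["s0", "s1", "s2"], "b": ["s3", "s4", "s5"]}
        _, common = estimate_dispersion(counts, groups)
        assert common < 0.02

    def test_nb_dispersion_recovered(self, rng):
        counts = self._counts(rng, phi=0.2)
        groups = {"a": ["s0", "s1", "s2"], "b": ["s3", "s4", "s5"]}
        _, common = estimate_dispersion(counts, groups)
        assert common == pytest.approx(0.2, abs=0.05)

    def test_underdispersed_gene_clipped_to_zero(self):
        counts = pd.DataFrame(
            {"s0": [100], "s1": [100], "s2": [100], "s3": [100]},
            index=["g0"],
        )
        tag, common = estimate_dispersion(
            counts, {"a": ["s0", "s1"], "b": ["s2", "s3"]}, shrink=0.0
        )
        assert tag.iloc[0] == 0.0 and common == 0.0

    def test_single_replicate_errors(self):
        counts = pd.DataFrame({"s0": [1], "s1": [1]})
        with pytest.raises(ValueError, match="single replicate"):
            estimate_dispersion(counts, {"a": ["s0"], "b": ["s1"]})


class TestExactTest:
    def test_identical_groups_p_one(self):
        counts = pd.DataFrame(
            {"s0": [50], "s1": [50], "s2": [50], "s3": [50]}, index=["g0"]
        )
        contrast = Contrast("c", ["s0", "s1"], ["s2", "s3"])
        factors = pd.Series(1.0, index=counts.columns)
        disp = pd.Series(0.1, index=counts.index)
        p = nb_exact_test(counts, contrast, factors, disp)
        assert p.iloc[0] == 1.0

    def test_zero_dispersion_equals_binomial_split(self, rng):
        """phi=0 reduces to the two-sided exact binomial split test."""
        for _ in range(50):
            s1, s2 = int(rng.integers(0, 60)), int(rng.integers(0, 60))
            n1, n2 = int(rng.integers(2, 5)), int(rng.integers(2, 5))
            mine = _conditional_exact_p(s1, s2, n1, n2, 0.0)
            ref = binomtest(s1, s1 + s2, n1 / (n1 + n2)).pvalue if s1 + s2 else 1.0
            assert mine == pytest.approx(ref, abs=1e-10)

    def test_zero_total_gives_p_one(self):
        assert _conditional_exact_p(0, 0, 3, 3, 0.2) == 1.0


class TestRunContrast:
    def _planted(self, seed=11, n_genes=2000, n_de=100):
        rng = np.random.default_rng(seed)
        design = default_design(3)
        base = rng.lognormal(np.log(80), 1.0, n_genes)
        de = np.zeros(n_genes, dtype=bool)
        de[:n_de] = True
        lfc = np.where(rng.random(n_genes) < 0.5, 2.0, -2.0) * de
        counts = {}
        for d in design:
            mean = base * np.exp2(lfc * (d.origin == "warm"))
            lam = rng.gamma(1 / 0.05, mean * 0.05)
            counts[d.sample_id] = rng.poisson(lam)
        df = pd.DataFrame(counts, index=[f"g{i}" for i in range(n_genes)])
        return df, design, de

    def test_planted_de_recovered_with_fdr_control(self):
        counts, design, truth = self._planted()
        de = run_contrast(counts, design, "origin")
        flagged = set(de.loc[de["is_deg"], "gene_id"])
        planted = {f"g{i}" for i in range(100)}
        assert len(flagged & planted) >= 80
        assert len(flagged - planted) <= 5

    def test_alpha_zero_flags_nothing(self):
        counts, design, _ = self._planted(n_genes=300, n_de=20)
        de = run_contrast(counts, design, "origin", alpha=0.0)
        assert not de["is_deg"].any()

    def test_swapped_groups_negate_effects_keep_p(self):
        counts, design, _ = self._planted(n_genes=300, n_de=20)
        fwd = run_contrast(counts, design, "origin")
        warm = [d.sample_id for d in design if d.origin == "warm"]
        cold = [d.sample_id for d in design if d.origin == "cold"]
        rev = run_contrast(counts, design, Contrast("rev", cold, warm))
        merged = fwd.merge(rev, on="gene_id", suffixes=("_f", "_r"))
        assert merged["log2_fc_f"].to_numpy() == pytest.approx(
            -merged["log2_fc_r"].to_numpy(), abs=1e-9
        )
        assert merged["magnitude_f"].to_numpy() == pytest.approx(
            -merged["magnitude_r"].to_numpy(), abs=1e-9
        )
        assert merged["p_f"].to_numpy() == pytest.approx(merged["p_r"].to_numpy(), abs=1e-9)
        assert (merged["is_deg_f"] == merged["is_deg_r"]).all()

    def test_standard_contrast_groups(self):
        design = default_design(3)
        c = build_contrast("treatment_cold", design)
        assert all(s.startswith("cold") and "heated" in s for s in c.group_a)
        assert len(c.group_a) == len(c.group_b) == 3


def test_deg_percentage_two_decimal_convention():
    assert deg_percentage(4465, 134863) == 3.31
    assert deg_percentage(1, 3) == 33.33
    with pytest.raises(ValueError):
        deg_percentage(1, 0)
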