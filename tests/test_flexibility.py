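"""Quantile binning and the CpG_O/E vs responsiveness statistics."""

import numpy as np
import pandas as pd
import pytest

from cpgflex.flexibility import (
    bin_frequency,
    bin_magnitude,
    component_contrast,
    flexibility_report,
    population_slopes,
    quantile_bins,
)
from cpgflex.mixture import ComponentSplit


def _cpg(values, prefix="g"):
    return pd.DataFrame(
        {"gene_id": [f"{prefix}{i}" for i in range(len(values))], "cpg_oe": values}
    )


def _de(genes, is_deg, magnitude=None):
    n = len(genes)
    return pd.DataFrame(
        {
            "gene_id": genes,
            "log2_fc": np.zeros(n),
            "p": np.ones(n),
            "fdr": np.where(is_deg, 0.01, 0.9),
            "is_deg": np.asarray(is_deg, dtype=bool),
            "magnitude": np.zeros(n) if magnitude is None else np.asarray(magnitude),
        }
    )


class TestQuantileBins:
    def test_even_split(self, rng):
        bins = quantile_bins(_cpg(rng.random(100)), 25)
        assert bins.value_counts().eq(4).all()

    def test_remainder_goes_to_lowest_bins(self, rng):
        bins = quantile_bins(_cpg(rng.random(101)), 25)
        sizes = bins.value_counts().sort_index()
        assert sizes.iloc[0] == 5 and (sizes.iloc[1:] == 4).all()

    def test_bins_ordered_by_cpg_oe(self, rng):
        cpg = _cpg(rng.random(200))
        bins = quantile_bins(cpg, 10)
        oe = cpg.set_index("gene_id")["cpg_oe"]
        maxes = [oe[bins.index[bins == b]].max() for b in range(10)]
        mins = [oe[bins.index[bins == b]].min() for b in range(10)]
        assert all(maxes[b] <= mins[b + 1] + 1e-12 for b in range(9))

    def test_ties_split_deterministically_by_gene_id(self):
        cpg = _cpg([0.5] * 10)
        b1 = quantile_bins(cpg, 5)
        b2 = quantile_bins(cpg.sample(frac=1, random_state=3), 5)
        assert b1.sort_index().equals(b2.sort_index())

    def test_too_few_genes_errors(self):
        with pytest.raises(ValueError):
            quantile_bins(_cpg([0.1, 0.2]), 5)


class TestBinFrequency:
    def test_planted_positive_trend(self, rng):
        oe = rng.uniform(0.1, 1.2, 5000)
        p_deg = 1 / (1 + np.exp(-(-4 + 3 * oe)))
        de = _de([f"g{i}" for i in range(5000)], rng.random(5000) < p_deg)
        cpg = _cpg(oe)
        table, corr = bin_frequency(quantile_bins(cpg, 25), cpg, de)
        assert corr.statistic > 0.5 and corr.p_value < 0.01

    def test_no_link_shows_no_trend_in_most_seeds(self):
        weak = 0
        for seed in range(5):
            rng = np.random.default_rng(2000 + seed)
            oe = rng.uniform(0.1, 1.2, 4000)
            de = _de([f"g{i}" for i in range(4000)], rng.random(4000) < 0.1)
            cpg = _cpg(oe)
            _, corr = bin_frequency(quantile_bins(cpg, 25), cpg, de)
            weak += abs(corr.statistic) < 0.3
        assert weak >= 4

    def test_deg_totals_conserved(self, rng):
        oe = rng.random(500)
        flags = rng.random(500) < 0.2
        cpg = _cpg(oe)
        table, _ = bin_frequency(quantile_bins(cpg, 25), cpg, _de(cpg["gene_id"], flags))
        assert table["n_deg"].sum() == flags.sum()

    def test_degs_planted_in_top_bin_stay_there(self, rng):
        oe = np.sort(rng.random(250))
        flags = np.zeros(250, dtype=bool)
        flags[-10:] = True  # the 10 highest-CpG genes
        cpg = _cpg(oe)
        table, _ = bin_frequency(quantile_bins(cpg, 25), cpg, _de(cpg["gene_id"], flags))
        assert table.iloc[-1]["n_deg"] == 10


class TestBinMagnitude:
    def test_constant_magnitudes_degenerate(self, rng):
        cpg = _cpg(rng.random(120))
        de = _de(cpg["gene_id"], [False] * 120, magnitude=np.full(120, 0.2))
        table, pearson, spearman, aov = bin_magnitude(quantile_bins(cpg, 12), cpg, de)
        assert pearson is None and spearman is None
        assert aov.statistic == 0.0 and aov.p_value == 1.0

    def test_monotone_planted_magnitude(self, rng):
        oe = rng.random(1200)
        de = _de(cpg_oe := [f"g{i}" for i in range(1200)], [False] * 1200, magnitude=oe + rng.normal(0, 0.01, 1200))
        cpg = _cpg(oe)
        table, pearson, spearman, aov = bin_magnitude(quantile_bins(cpg, 12), cpg, de)
        assert spearman.statistic == pytest.approx(1.0)
        assert aov.p_value < 1e-6

    def test_sign_of_magnitude_irrelevant(self, rng):
        oe = rng.random(600)
        mag = rng.normal(0, 0.3, 600)
        cpg = _cpg(oe)
        t1, *_ = bin_magnitude(quantile_bins(cpg, 12), cpg, _de(cpg["gene_id"], [False] * 600, mag))
        t2, *_ = bin_magnitude(quantile_bins(cpg, 12), cpg, _de(cpg["gene_id"], [False] * 600, -mag))
        assert t1["mean_magnitude"].to_numpy() == pytest.approx(t2["mean_magnitude"].to_numpy())


class TestComponentContrast:
    def _split(self, cpg, threshold):
        comp = {g: ("low" if v < threshold else "high") for g, v in zip(cpg["gene_id"], cpg["cpg_oe"])}
        n_low = sum(1 for v in comp.values() if v == "low")
        return ComponentSplit(threshold, comp, n_low, len(comp) - n_low, 0.0)

    def test_identical_bin_counts_p_one(self):
        table = pd.DataFrame(
            {"bin": range(6), "mean_cpg_oe": [0.1, 0.2, 0.3, 0.7, 0.8, 0.9], "n_deg": [5] * 6}
        )
        cpg = _cpg([0.1, 0.9])
        res = component_contrast(table, self._split(cpg, 0.5), _de(cpg["gene_id"], [0, 0]))
        assert res.frequency_t.p_value == 1.0

    def test_planted_rate_difference_detected(self, rng):
        oe = rng.uniform(0.1, 1.2, 10_000)
        flags = rng.random(10_000) < np.where(oe >= 0.6, 0.2, 0.1)
        cpg = _cpg(oe)
        de = _de(cpg["gene_id"], flags)
        table, _ = bin_frequency(quantile_bins(cpg, 25), cpg, de)
        res = component_contrast(table, self._split(cpg, 0.6), de)
        assert res.frequency_t.p_value < 0.05
        assert res.freq_mean_high > res.freq_mean_low

    def test_single_bin_component_skips_frequency_test(self, rng):
        table = pd.DataFrame(
            {"bin": range(4), "mean_cpg_oe": [0.1, 0.6, 0.7, 0.8], "n_deg": [1, 2, 3, 4]}
        )
        cpg = _cpg([0.1, 0.8, 0.85, 0.9, 0.95])
        res = component_contrast(table, self._split(cpg, 0.5), _de(cpg["gene_id"], [0] * 5))
        assert res.frequency_t is None and "skipped" in res.frequency_skipped


class TestPopulationSlopes:
    def _table(self, counts):
        return pd.DataFrame(
            {"bin": range(len(counts)), "mean_cpg_oe": np.linspace(0.2, 1.0, len(counts)), "n_deg": counts}
        )

    def test_identical_tables_ratio_one(self):
        t = self._table([1, 3, 5, 7, 9])
        assert population_slopes(t, t)[2] == pytest.approx(1.0)

    def test_tripled_counts_triple_the_ratio(self):
        t = self._table([1, 3, 5, 7, 9])
        t3 = t.assign(n_deg=t["n_deg"] * 3)
        assert population_slopes(t3, t)[2] == pytest.approx(3.0)

    def test_zero_denominator_slope_flagged(self):
        t = self._table([1, 3, 5, 7, 9])
        flat = self._table([4, 4, 4, 4, 4])
        assert np.isnan(population_slopes(t, flat)[2])


def test_flexibility_report_end_to_end(rng):
    oe = rng.uniform(0.1, 1.2, 800)
    p_deg = 1 / (1 + np.exp(-(-4 + 3 * oe)))
    de = _de([f"g{i}" for i in range(800)], rng.random(800) < p_deg, magnitude=0.1 * oe)
    cpg = _cpg(oe)
    comp = {g: ("low" if v < 0.67 else "high") for g, v in zip(cpg["gene_id"], oe)}
    split = ComponentSplit(0.67, comp, sum(v == "low" for v in comp.values()), 0, 0.0)
    rep = flexibility_report(cpg, de, "origin", split=split)
    assert len(rep.frequency_bins) == 25 and len(rep.magnitude_bins) == 12
    assert rep.frequency_bins["n_deg"].sum() == de["is_deg"].sum()
    assert rep.frequency_corr.statistic > 0
    assert set(rep.frequency_bins["component"]) == {"low", "high"}
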