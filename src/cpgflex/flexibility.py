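"""Quantile-bin analyses linking CpG_O/E to expression responsiveness.

Genes are ranked by CpG_O/E and cut into equally sized quantile bins
(25 for the DEG-frequency analysis, 12 for the magnitude analysis, as
in the source study design). Per bin the analysis reports the DEG
count or the mean absolute expression magnitude, correlates it with
the bin's mean CpG_O/E, contrasts the low- vs high-CpG components by
Welch t, and compares the frequency-vs-CpG_O/E slopes of two
populations. Magnitudes are averaged as absolute values within bins:
signed log ratios of genes moving in opposite directions would cancel.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .mixture import ComponentSplit
from .stats import (
    TestResult,
    anova_oneway,
    correlation,
    linear_fit,
    welch_t_test,
)

logger = logging.getLogger(__name__)

N_BINS_FREQUENCY = 25
N_BINS_MAGNITUDE = 12


@dataclass
class ComponentContrast:
    frequency_t: TestResult | None  # per-bin DEG counts, low vs high bins
    magnitude_t: TestResult | None  # per-gene |magnitude|, low vs high genes
    freq_mean_low: float = float("nan")
    freq_sd_low: float = float("nan")
    freq_mean_high: float = float("nan")
    freq_sd_high: float = float("nan")
    mag_mean_low: float = float("nan")
    mag_mean_high: float = float("nan")
    frequency_skipped: str | None = None


@dataclass
class FlexReport:
    """All bin-level statistics for one contrast."""

    contrast: str
    frequency_bins: pd.DataFrame
    frequency_corr: TestResult | None
    magnitude_bins: pd.DataFrame
    magnitude_pearson: TestResult | None
    magnitude_spearman: TestResult | None
    magnitude_anova: TestResult | None
    component: ComponentContrast | None = None
    notes: list[str] = field(default_factory=list)


def quantile_bins(cpg: pd.DataFrame, n_bins: int) -> pd.Series:
    """Assign genes to contiguous CpG_O/E quantile bins.

    Genes are sorted by (cpg_oe, gene_id) — the id tie-break makes the
    assignment deterministic — and split into ``n_bins`` groups whose
    sizes differ by at most one, extra genes going to the lowest bins.
    Returns a gene_id-indexed Series of 0-based bin indices.
    """
    n = len(cpg)
    if n < n_bins:
        raise ValueError(f"cannot form {n_bins} bins from {n} genes")
    ordered = cpg.sort_values(["cpg_oe", "gene_id"], kind="mergesort")
    base, rem = divmod(n, n_bins)
    sizes = [base + 1] * rem + [base] * (n_bins - rem)
    idx = np.repeat(np.arange(n_bins), sizes)
    return pd.Series(idx, index=ordered["gene_id"], name="bin")


def _bin_table(bins: pd.Series, cpg: pd.DataFrame, de: pd.DataFrame) -> pd.DataFrame:
    oe = cpg.set_index("gene_id")["cpg_oe"]
    dei = de.set_index("gene_id")
    shared = bins.index.intersection(dei.index)
    rows = []
    for b in range(int(bins.max()) + 1):
        genes = bins.index[bins == b]
        in_de = genes.intersection(dei.index)
        mags = dei.loc[in_de, "magnitude"].abs()
        rows.append(
            {
                "bin": b,
                "n_genes": len(genes),
                "mean_cpg_oe": float(oe.loc[genes].mean()),
                "n_deg": int(dei.loc[in_de, "is_deg"].sum()),
                "mean_magnitude": float(mags.mean()) if len(mags) else float("nan"),
                "se_magnitude": float(mags.std(ddof=1) / np.sqrt(len(mags)))
                if len(mags) > 1
                else float("nan"),
            }
        )
    df = pd.DataFrame(rows)
    assert int(df["n_deg"].sum()) == int(dei.loc[shared, "is_deg"].sum())
    return df


def bin_frequency(
    bins: pd.Series, cpg: pd.DataFrame, de: pd.DataFrame
) -> tuple[pd.DataFrame, TestResult | None]:
    """Per-bin DEG counts and their Pearson correlation with CpG_O/E."""
    table = _bin_table(bins, cpg, de)
    if len(table) < 3:
        raise ValueError("need at least 3 bins for the frequency analysis")
    corr = None
    if table["n_deg"].sum() == 0 or table["n_deg"].nunique() == 1:
        logger.warning("bin_frequency: DEG counts constant; correlation undefined")
    else:
        corr = correlation(table["mean_cpg_oe"], table["n_deg"], "pearson")
    return table, corr


def bin_magnitude(
    bins: pd.Series, cpg: pd.DataFrame, de: pd.DataFrame
) -> tuple[pd.DataFrame, TestResult | None, TestResult | None, TestResult | None]:
    """Per-bin mean |magnitude| ± SE, correlations and one-way ANOVA."""
    table = _bin_table(bins, cpg, de)
    mags = de.set_index("gene_id")["magnitude"].abs()
    ok = table["mean_magnitude"].notna()
    pearson = spearman = aov = None
    if ok.sum() >= 3 and table.loc[ok, "mean_magnitude"].nunique() > 1:
        pearson = correlation(
            table.loc[ok, "mean_cpg_oe"], table.loc[ok, "mean_magnitude"], "pearson"
        )
        spearman = correlation(
            table.loc[ok, "mean_cpg_oe"], table.loc[ok, "mean_magnitude"], "spearman"
        )
    else:
        logger.warning("bin_magnitude: per-bin magnitudes constant or sparse; correlations undefined")
    groups = []
    for b in table["bin"]:
        genes = bins.index[bins == b].intersection(mags.index)
        g = mags.loc[genes].to_numpy()
        if g.size < 2:
            logger.warning("bin_magnitude: bin %d has < 2 genes; excluded from ANOVA", b)
            continue
        groups.append(g)
    if len(groups) >= 2:
        aov = anova_oneway(groups)
    return table, pearson, spearman, aov


def component_contrast(
    bin_table: pd.DataFrame, split: ComponentSplit, de: pd.DataFrame
) -> ComponentContrast:
    """Low- vs high-CpG component differences.

    A bin belongs to the component of its mean CpG_O/E relative to the
    classification threshold. DEG frequency is compared across bins;
    per-gene |magnitude| across the genes of each component.
    """
    low_bins = bin_table[bin_table["mean_cpg_oe"] < split.threshold]
    high_bins = bin_table[bin_table["mean_cpg_oe"] >= split.threshold]
    freq_t = None
    skipped = None
    if len(low_bins) < 2 or len(high_bins) < 2:
        skipped = (
            f"frequency test skipped: components hold {len(low_bins)} and "
            f"{len(high_bins)} bins (need >= 2 each)"
        )
        logger.warning("component_contrast: %s", skipped)
    else:
        freq_t = welch_t_test(low_bins["n_deg"], high_bins["n_deg"])
    dei = de.set_index("gene_id")
    comp = pd.Series(split.assignment)
    shared = dei.index.intersection(comp.index)
    mag = dei.loc[shared, "magnitude"].abs()
    low_m = mag[comp.loc[shared] == "low"]
    high_m = mag[comp.loc[shared] == "high"]
    mag_t = None
    if len(low_m) >= 2 and len(high_m) >= 2:
        mag_t = welch_t_test(low_m, high_m)
    return ComponentContrast(
        frequency_t=freq_t,
        magnitude_t=mag_t,
        freq_mean_low=float(low_bins["n_deg"].mean()) if len(low_bins) else float("nan"),
        freq_sd_low=float(low_bins["n_deg"].std(ddof=1)) if len(low_bins) > 1 else float("nan"),
        freq_mean_high=float(high_bins["n_deg"].mean()) if len(high_bins) else float("nan"),
        freq_sd_high=float(high_bins["n_deg"].std(ddof=1)) if len(high_bins) > 1 else float("nan"),
        mag_mean_low=float(low_m.mean()) if len(low_m) else float("nan"),
        mag_mean_high=float(high_m.mean()) if len(high_m) else float("nan"),
        frequency_skipped=skipped,
    )


def population_slopes(
    bin_table_a: pd.DataFrame, bin_table_b: pd.DataFrame
) -> tuple[float, float, float]:
    """OLS slopes of n_deg vs mean CpG_O/E for two populations + ratio."""
    if len(bin_table_a) != len(bin_table_b):
        raise ValueError("bin tables must share the same number of bins")
    fa = linear_fit(bin_table_a["mean_cpg_oe"], bin_table_a["n_deg"])
    fb = linear_fit(bin_table_b["mean_cpg_oe"], bin_table_b["n_deg"])
    ratio = fa.slope / fb.slope if fb.slope != 0 else float("nan")
    if fb.slope == 0:
        logger.warning("population_slopes: denominator slope is 0; ratio undefined")
    return fa.slope, fb.slope, ratio


def flexibility_report(
    cpg: pd.DataFrame,
    de: pd.DataFrame,
    contrast_name: str,
    split: ComponentSplit | None = None,
    n_bins_frequency: int = N_BINS_FREQUENCY,
    n_bins_magnitude: int = N_BINS_MAGNITUDE,
) -> FlexReport:
    """Run the full bin analysis for one contrast.

    Binning uses the genes present in both the CpG profile and the DE
    table, so every DEG is accounted for in exactly one bin.
    """
    shared = cpg[cpg["gene_id"].isin(de["gene_id"])]
    if shared.empty:
        raise ValueError("CpG profile and DE table share no genes")
    notes = []
    dropped = len(cpg) - len(shared)
    if dropped:
        notes.append(f"{dropped} profiled genes absent from the DE table were dropped")
    bins_f = quantile_bins(shared, n_bins_frequency)
    freq_table, freq_corr = bin_frequency(bins_f, shared, de)
    bins_m = quantile_bins(shared, n_bins_magnitude)
    mag_table, pearson, spearman, aov = bin_magnitude(bins_m, shared, de)
    comp = None
    if split is not None:
        comp = component_contrast(freq_table, split, de)
        freq_table = freq_table.assign(
            component=np.where(freq_table["mean_cpg_oe"] < split.threshold, "low", "high")
        )
        mag_table = mag_table.assign(
            component=np.where(mag_table["mean_cpg_oe"] < split.threshold, "low", "high")
        )
    return FlexReport(
        contrast=contrast_name,
        frequency_bins=freq_table,
        frequency_corr=freq_corr,
        magnitude_bins=mag_table,
        magnitude_pearson=pearson,
        magnitude_spearman=spearman,
        magnitude_anova=aov,
        component=comp,
        notes=notes,
    )
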