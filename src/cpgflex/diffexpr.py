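"""Simplified negative-binomial two-group differential expression.

The chain mirrors the standard RNA-seq workflow: drop genes below 1
CPM in fewer than three samples, normalize library sizes by the
trimmed mean of M-values (TMM), estimate NB dispersions by moments
with shrinkage toward the median, and test each gene with a
conditional exact test: counts are scaled to a common effective
library size and summed within groups, and under the null of equal
means the low-group total given the overall total follows a
beta-binomial-type law whose probabilities depend only on the group
sizes and the dispersion. The two-sided p-value sums the conditional
probabilities of outcomes no more probable than the observed split.
With zero dispersion this reduces exactly to a binomial split test.

Four contrasts cover a 2 origin x 2 treatment design: thermal origin
(warm vs cold, treatments pooled), experimental treatment (heated vs
control, origins pooled), and the treatment contrast within each
origin separately.

The per-gene magnitude of differential expression is
log10((mean CPM of group A + c) / (mean CPM of group B + c)) with a
0.5-CPM pseudocount; the fold change is the same ratio in log2.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

from .io import SampleDesign
from .stats import bh_fdr

logger = logging.getLogger(__name__)

CONTRAST_NAMES = ("origin", "treatment_all", "treatment_cold", "treatment_warm")
MAGNITUDE_PSEUDOCOUNT = 0.5  # CPM units


@dataclass
class Contrast:
    """Two disjoint sample groups; A is the numerator of the ratio."""

    name: str
    group_a: list[str]
    group_b: list[str]

    def __post_init__(self):
        if set(self.group_a) & set(self.group_b):
            raise ValueError(f"contrast {self.name}: groups overlap")
        if len(self.group_a) < 2 or len(self.group_b) < 2:
            raise ValueError(f"contrast {self.name}: each group needs >= 2 samples")


def build_contrast(name: str, design: list[SampleDesign]) -> Contrast:
    """Standard contrast for the 2 origin x 2 treatment design.

    origin: warm vs cold (all treatments); treatment_all: heated vs
    control (all origins); treatment_cold / treatment_warm: heated vs
    control within one origin.
    """
    if name == "origin":
        a = [d.sample_id for d in design if d.origin == "warm"]
        b = [d.sample_id for d in design if d.origin == "cold"]
    elif name == "treatment_all":
        a = [d.sample_id for d in design if d.treatment == "heated"]
        b = [d.sample_id for d in design if d.treatment == "control"]
    elif name in ("treatment_cold", "treatment_warm"):
        org = name.split("_")[1]
        a = [d.sample_id for d in design if d.origin == org and d.treatment == "heated"]
        b = [d.sample_id for d in design if d.origin == org and d.treatment == "control"]
    else:
        raise ValueError(f"unknown contrast {name!r}; expected one of {CONTRAST_NAMES}")
    return Contrast(name, a, b)


def cpm(counts: pd.DataFrame, lib_sizes: pd.Series | None = None) -> pd.DataFrame:
    if lib_sizes is None:
        lib_sizes = counts.sum(axis=0)
    return counts / lib_sizes * 1e6


def cpm_filter(
    counts: pd.DataFrame, min_cpm: float = 1.0, min_samples: int = 3
) -> pd.DataFrame:
    """Keep genes with CPM >= min_cpm in at least min_samples samples."""
    lib = counts.sum(axis=0)
    if (lib <= 0).any():
        raise ValueError("library sizes must be positive")
    keep = (cpm(counts) >= min_cpm).sum(axis=1) >= min_samples
    if not keep.any():
        raise ValueError("all genes removed by the CPM filter")
    logger.info("cpm_filter: kept %d of %d genes", int(keep.sum()), len(keep))
    return counts.loc[keep]


def tmm_factors(
    counts: pd.DataFrame, trim_m: float = 0.30, trim_a: float = 0.05
) -> pd.Series:
    """Trimmed-mean-of-M-values normalization factors.

    The reference is the sample whose 75th-percentile CPM is closest
    to the across-sample mean of that quantile. For every sample, M
    (log2 CPM ratio vs reference) and A (mean log2 CPM) are computed
    over genes positive in both; the top/bottom ``trim_m`` of M and
    ``trim_a`` of A are trimmed and the factor is the precision-
    weighted mean M, de-logged. Factors are rescaled to geometric
    mean 1.
    """
    if counts.shape[1] < 2:
        raise ValueError("TMM needs at least 2 samples")
    lib = counts.sum(axis=0).astype(float)
    q75 = (counts / lib).quantile(0.75)
    ref = (q75 - q75.mean()).abs().idxmin()
    yr = counts[ref].to_numpy(float)
    nr = lib[ref]
    factors = {}
    for s in counts.columns:
        if s == ref:
            factors[s] = 1.0
            continue
        y = counts[s].to_numpy(float)
        n = lib[s]
        pos = (y > 0) & (yr > 0)
        if not pos.any():
            logger.warning("tmm_factors: sample %r shares no positive genes with reference", s)
            factors[s] = 1.0
            continue
        yp, yrp = y[pos], yr[pos]
        m = np.log2((yp / n) / (yrp / nr))
        aa = 0.5 * np.log2((yp / n) * (yrp / nr))
        w = (n - yp) / (n * yp) + (nr - yrp) / (nr * yrp)
        fin = np.isfinite(m) & np.isfinite(aa)
        m, aa, w = m[fin], aa[fin], w[fin]
        if m.size == 0:
            factors[s] = 1.0
            continue
        n_g = m.size
        m_rank = m.argsort().argsort()
        a_rank = aa.argsort().argsort()
        lo_m, hi_m = np.floor(n_g * trim_m) + 1, n_g + 1 - np.floor(n_g * trim_m)
        lo_a, hi_a = np.floor(n_g * trim_a) + 1, n_g + 1 - np.floor(n_g * trim_a)
        keep = (
            (m_rank + 1 >= lo_m) & (m_rank + 1 <= hi_m)
            & (a_rank + 1 >= lo_a) & (a_rank + 1 <= hi_a)
        )
        if not keep.any() or w[keep].sum() == 0:
            factors[s] = 1.0
            continue
        f = np.sum(m[keep] / w[keep]) / np.sum(1.0 / w[keep])
        factors[s] = float(2.0**f)
    fac = pd.Series(factors)[counts.columns]
    fac = fac / np.exp(np.log(fac).mean())
    return fac


def estimate_dispersion(
    counts: pd.DataFrame,
    groups: dict[str, list[str]],
    factors: pd.Series | None = None,
    shrink: float = 0.7,
) -> tuple[pd.Series, float]:
    """Method-of-moments NB dispersion per gene, shrunk to the median.

    Counts are scaled by effective library size; within each group the
    moment estimate phi = (s^2 - mu)/mu^2 is computed and the
    df-weighted average across groups, clipped at 0, gives the
    per-gene raw estimate. The common dispersion is the mean of the
    raw estimates (per-gene moment ratios are heavily right-skewed at
    few replicates, so the median would sit well below the true
    dispersion and make the exact test liberal); the tagwise value is
    (1 - shrink)*raw + shrink*common.
    """
    for name, samples in groups.items():
        if len(samples) < 2:
            raise ValueError(f"group {name!r} has a single replicate")
    lib = counts.sum(axis=0).astype(float)
    if factors is None:
        factors = pd.Series(1.0, index=counts.columns)
    eff = lib * factors
    scale = np.exp(np.log(eff).mean())
    scaled = counts / eff * scale
    num = pd.Series(0.0, index=counts.index)
    den = 0.0
    for samples in groups.values():
        sub = scaled[samples]
        mu = sub.mean(axis=1)
        s2 = sub.var(axis=1, ddof=1)
        df = len(samples) - 1
        with np.errstate(divide="ignore", invalid="ignore"):
            phi = (s2 - mu) / mu**2
        num += df * phi.fillna(0.0).replace([np.inf, -np.inf], 0.0)
        den += df
    raw = (num / den).clip(lower=0.0)
    common = float(raw.mean())
    tagwise = (1 - shrink) * raw + shrink * common
    return tagwise, common


def _conditional_exact_p(s1: int, s2: int, n1: int, n2: int, phi: float) -> float:
    """Two-sided exact p for the split (s1, s2) of the group totals.

    Under equal per-sample NB means, the conditional law of s1 given
    s1 + s2 = t has weights C(k + n1/phi - 1, k) * C(t - k + n2/phi - 1, t - k)
    (the shared NB success probability cancels); phi = 0 gives the
    binomial limit with success probability n1/(n1+n2).
    """
    t = s1 + s2
    if t == 0:
        return 1.0
    k = np.arange(t + 1)
    if phi < 1e-10:
        logw = (
            k * np.log(n1 / (n1 + n2))
            + (t - k) * np.log(n2 / (n1 + n2))
            - gammaln(k + 1)
            - gammaln(t - k + 1)
            + gammaln(t + 1)
        )
    else:
        r1, r2 = n1 / phi, n2 / phi
        logw = (
            gammaln(k + r1) - gammaln(k + 1)
            + gammaln(t - k + r2) - gammaln(t - k + 1)
        )
    logw = logw - logsumexp(logw)
    w = np.exp(logw)
    p = float(w[w <= w[s1] * (1 + 1e-7)].sum())
    if p > 1.0 - 1e-9:
        return 1.0
    return p


def nb_exact_test(
    counts: pd.DataFrame,
    contrast: Contrast,
    factors: pd.Series,
    dispersions: pd.Series,
) -> pd.Series:
    """Per-gene conditional exact NB p-values for a two-group contrast.

    Counts are rescaled to the geometric-mean effective library size
    (pseudo-counts), rounded, and summed within each group before
    testing.
    """
    samples = contrast.group_a + contrast.group_b
    lib = counts[samples].sum(axis=0).astype(float)
    eff = lib * factors[samples]
    common_size = np.exp(np.log(eff).mean())
    pseudo = counts[samples] / eff * common_size
    s_a = pseudo[contrast.group_a].sum(axis=1).round().astype(np.int64)
    s_b = pseudo[contrast.group_b].sum(axis=1).round().astype(np.int64)
    n1, n2 = len(contrast.group_a), len(contrast.group_b)
    pvals = np.array(
        [
            _conditional_exact_p(int(a), int(b), n1, n2, float(phi))
            for a, b, phi in zip(s_a, s_b, dispersions[counts.index])
        ]
    )
    return pd.Series(pvals, index=counts.index, name="p")


def run_contrast(
    counts: pd.DataFrame,
    design: list[SampleDesign],
    contrast: str | Contrast,
    alpha: float = 0.05,
    min_cpm: float = 1.0,
    min_samples: int = 3,
) -> pd.DataFrame:
    """Full DE chain for one contrast; one row per filtered gene.

    Columns: gene_id, mean_a, mean_b (normalized CPM), log2_fc,
    magnitude (log10 ratio, 0.5-CPM pseudocount), p, fdr, is_deg.
    """
    if isinstance(contrast, str):
        contrast = build_contrast(contrast, design)
    samples = contrast.group_a + contrast.group_b
    missing = [s for s in samples if s not in counts.columns]
    if missing:
        raise ValueError(f"contrast {contrast.name}: samples missing from counts: {missing}")
    sub = counts[samples]
    filtered = cpm_filter(sub, min_cpm=min_cpm, min_samples=min_samples)
    factors = tmm_factors(filtered)
    groups = {"a": contrast.group_a, "b": contrast.group_b}
    tagwise, _common = estimate_dispersion(filtered, groups, factors)
    p = nb_exact_test(filtered, contrast, factors, tagwise)
    fdr = bh_fdr(p.to_numpy())
    eff = filtered.sum(axis=0).astype(float) * factors
    norm_cpm = filtered / eff * 1e6
    mean_a = norm_cpm[contrast.group_a].mean(axis=1)
    mean_b = norm_cpm[contrast.group_b].mean(axis=1)
    c = MAGNITUDE_PSEUDOCOUNT
    ratio = (mean_a + c) / (mean_b + c)
    out = pd.DataFrame(
        {
            "gene_id": filtered.index,
            "mean_a": mean_a.to_numpy(),
            "mean_b": mean_b.to_numpy(),
            "log2_fc": np.log2(ratio.to_numpy()),
            "magnitude": np.log10(ratio.to_numpy()),
            "p": p.to_numpy(),
            "fdr": fdr,
            "is_deg": fdr < alpha,
        }
    ).reset_index(drop=True)
    return out


def read_de_table(path) -> pd.DataFrame:
    """Import an external DE table (gene_id, logFC/log2_fc, p, fdr).

    Lets any DE tool's output feed the downstream flexibility analysis;
    the magnitude is reconstructed as log10(2) * log2 fold change.
    """
    df = pd.read_csv(path, sep="\t")
    if "logFC" in df.columns and "log2_fc" not in df.columns:
        df = df.rename(columns={"logFC": "log2_fc"})
    required = {"gene_id", "log2_fc", "p", "fdr"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"DE table missing columns {sorted(missing)}")
    if "magnitude" not in df.columns:
        df["magnitude"] = df["log2_fc"] * np.log10(2.0)
    if "is_deg" not in df.columns:
        df["is_deg"] = df["fdr"] < 0.05
    return df


def deg_percentage(n_deg: int, n_total: int) -> float:
    """DEG share of a gene universe, in percent (2-decimal convention)."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    return round(100.0 * n_deg / n_total, 2)


def summarize_contrasts(
    de_tables: dict[str, pd.DataFrame], n_total_genes: int | None = None
) -> dict:
    """DEG counts per contrast with percentages of the expressed set
    and, when given, of the full transcriptome."""
    out: dict = {}
    for name, df in de_tables.items():
        n_deg = int(df["is_deg"].sum())
        n_expr = int(len(df))
        entry = {
            "n_deg": n_deg,
            "n_expressed": n_expr,
            "pct_of_expressed": deg_percentage(n_deg, n_expr) if n_expr else float("nan"),
        }
        if n_total_genes:
            entry["pct_of_total"] = deg_percentage(n_deg, n_total_genes)
        out[name] = entry
    return out
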