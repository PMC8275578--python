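"""Statistical primitives shared by the enrichment, DE and binning stages.

The two-sided Fisher exact test and the Benjamini-Hochberg step-up are
implemented here directly (they drive the enrichment and DEG calls and
are checked against enumeration oracles in the test suite); the routine
fits — correlations, Welch t, one-way ANOVA, OLS — delegate to scipy.
All tests are two-sided.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from scipy.stats import hypergeom

# Relative slack when comparing table probabilities to the observed
# table's probability, matching R fisher.test's tolerance.
_FISHER_REL_EPS = 1e-7


@dataclass
class TestResult:
    statistic: float
    p_value: float
    df: float | None = None
    n: int | None = None


@dataclass
class FisherResult:
    odds_ratio: float
    p_value: float
    zero_margin: bool = False


@dataclass
class LinearFit:
    slope: float
    intercept: float
    r_squared: float


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> FisherResult:
    """Two-sided Fisher exact test on the 2x2 table [[a, b], [c, d]].

    The p-value sums hypergeometric probabilities (margins fixed) of
    all tables no more probable than the observed one. The odds ratio
    is the sample odds ratio (a*d)/(b*c), with inf when only b*c is
    zero and NaN when both products vanish. A zero margin makes the
    table degenerate: p = 1 and the odds ratio is undefined.
    """
    for v in (a, b, c, d):
        if v < 0 or int(v) != v:
            raise ValueError("counts must be non-negative integers")
    a, b, c, d = int(a), int(b), int(c), int(d)
    n_tot = a + b + c + d
    r1, c1 = a + b, a + c
    if r1 == 0 or c1 == 0 or r1 == n_tot or c1 == n_tot:
        return FisherResult(odds_ratio=float("nan"), p_value=1.0, zero_margin=True)
    ad, bc = a * d, b * c
    if bc == 0:
        odds = float("nan") if ad == 0 else float("inf")
    else:
        odds = ad / bc
    k_min = max(0, c1 - (n_tot - r1))
    k = np.arange(k_min, min(r1, c1) + 1)
    pmf = hypergeom.pmf(k, n_tot, c1, r1)
    p_obs = pmf[a - k_min]
    p = float(pmf[pmf <= p_obs * (1 + _FISHER_REL_EPS)].sum())
    if p > 1.0 - 1e-9:  # absorb float error when every table is kept
        p = 1.0
    return FisherResult(odds_ratio=odds, p_value=p)


def bh_fdr(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.minimum(q, 1.0)
    out = np.empty(m)
    out[order] = q
    return out


def _check_pair(x, y, min_n: int):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < min_n:
        raise ValueError(f"need at least {min_n} observations, got {x.size}")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("inputs must be finite")
    return x, y


def correlation(x, y, method: str = "pearson") -> TestResult:
    """Pearson or Spearman correlation with its two-sided p-value."""
    x, y = _check_pair(x, y, 3)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant vector")
    if method == "pearson":
        r, p = sps.pearsonr(x, y)
    elif method == "spearman":
        r, p = sps.spearmanr(x, y)
    else:
        raise ValueError(f"unknown method {method!r}")
    return TestResult(statistic=float(r), p_value=float(p), df=x.size - 2, n=x.size)


def welch_t_test(x, y, pooled: bool = False) -> TestResult:
    """Two-sample t test, Welch (unequal variances) by default."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each sample needs at least 2 observations")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("inputs must be finite")
    if x.var(ddof=1) == 0 and y.var(ddof=1) == 0:
        # exact-equality branch: no within-sample variability
        if x.mean() == y.mean():
            return TestResult(0.0, 1.0, df=x.size + y.size - 2, n=x.size + y.size)
        return TestResult(
            float(np.sign(x.mean() - y.mean()) * np.inf), 0.0,
            df=x.size + y.size - 2, n=x.size + y.size,
        )
    res = sps.ttest_ind(x, y, equal_var=pooled)
    return TestResult(
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        df=float(res.df),
        n=x.size + y.size,
    )


def anova_oneway(groups) -> TestResult:
    """One-way fixed-effects ANOVA across >= 2 groups."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    for g in groups:
        if g.size < 2:
            raise ValueError("each group needs at least 2 observations")
        if not np.isfinite(g).all():
            raise ValueError("inputs must be finite")
    n = sum(g.size for g in groups)
    df_b, df_w = len(groups) - 1, n - len(groups)
    grand = np.concatenate(groups).mean()
    ss_b = sum(g.size * (g.mean() - grand) ** 2 for g in groups)
    ss_w = sum(((g - g.mean()) ** 2).sum() for g in groups)
    scale = max(1.0, grand * grand) * n
    if ss_b <= 1e-14 * scale:  # group means numerically identical
        return TestResult(0.0, 1.0, df=df_b, n=n)
    if ss_w <= 1e-14 * scale:
        return TestResult(float("inf"), 0.0, df=df_b, n=n)
    f, p = sps.f_oneway(*groups)
    return TestResult(statistic=float(f), p_value=float(p), df=df_b, n=n)


def linear_fit(x, y) -> LinearFit:
    """Ordinary least squares line y = slope*x + intercept."""
    x, y = _check_pair(x, y, 3)
    if np.ptp(x) == 0:
        raise ValueError("linear fit undefined for constant x")
    res = sps.linregress(x, y)
    return LinearFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
    )
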