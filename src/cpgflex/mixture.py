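"""Gaussian mixture modelling of the CpG_O/E distribution.

The per-gene CpG_O/E distribution of a transcriptome is typically
bimodal: a low-CpG component of historically hypermethylated genes and
a high-CpG component of hypomethylated ones. This module fits one- and
two-component Gaussian models by maximum likelihood (EM with unequal
variances and multiple restarts for k=2), compares them by BIC and raw
log-likelihood, finds the point between the component means where the
two weighted component densities intersect, and uses that point as an
objective threshold to assign each gene to the low or high component.

Components are always reported in ascending order of mean, so
component 1 is the low-CpG (hypermethylation-biased) component
regardless of EM label switching.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm

logger = logging.getLogger(__name__)

SIGMA_FLOOR = 1e-4


@dataclass
class MixtureFit:
    """Maximum-likelihood fit of a k-component Gaussian mixture."""

    k: int
    lambda_: np.ndarray  # mixing proportions, sum to 1
    mu: np.ndarray  # component means, ascending
    sigma: np.ndarray  # component standard deviations
    loglik: float
    bic: float
    n: int
    converged: bool
    n_iter: int
    loglik_trace: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def n_params(self) -> int:
        # k means + k sigmas + (k-1) free mixing proportions
        return 3 * self.k - 1


@dataclass
class ModelComparison:
    loglik_1: float
    loglik_2: float
    bic_1: float
    bic_2: float
    delta_bic: float  # bic_2 - bic_1; negative favours the mixture
    selected_k: int


@dataclass
class ComponentSplit:
    """Threshold-based low/high component assignment."""

    threshold: float
    assignment: dict[str, str]  # gene_id -> "low" | "high"
    n_low: int
    n_high: int
    frac_depleted: float  # fraction of genes with cpg_oe < 1.0


def _bic(loglik: float, n_params: int, n: int) -> float:
    return n_params * np.log(n) - 2.0 * loglik


def _validate(x: np.ndarray, min_n: int) -> np.ndarray:
    x = np.asarray(x, dtype=float).ravel()
    if not np.isfinite(x).all():
        raise ValueError("input contains non-finite values (NaN/inf)")
    if x.size < min_n:
        raise ValueError(f"insufficient data: n={x.size} < {min_n}")
    return x


def fit_single_gaussian(x) -> MixtureFit:
    """MLE single-Gaussian fit (sigma uses divisor n, floored)."""
    x = _validate(x, 10)
    mu = float(x.mean())
    sigma = float(x.std(ddof=0))
    if sigma < SIGMA_FLOOR:
        logger.warning("degenerate variance: sigma clipped to floor %g", SIGMA_FLOOR)
        sigma = SIGMA_FLOOR
    loglik = float(norm.logpdf(x, mu, sigma).sum())
    fit = MixtureFit(
        k=1,
        lambda_=np.array([1.0]),
        mu=np.array([mu]),
        sigma=np.array([sigma]),
        loglik=loglik,
        bic=_bic(loglik, 2, x.size),
        n=x.size,
        converged=True,
        n_iter=0,
    )
    return fit


def _em_run(
    x: np.ndarray,
    lam: np.ndarray,
    mu: np.ndarray,
    sigma: np.ndarray,
    tol: float,
    max_iter: int,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float, bool, int, np.ndarray]:
    """One EM run from the given start; returns params + loglik trace.

    Convergence: per-iteration log-likelihood gain below
    ``tol * (1 + |loglik|)`` (relative, so the criterion does not
    tighten with sample size).
    """
    n = x.size
    trace = np.empty(max_iter)
    prev = -np.inf
    converged = False
    it = 0
    half_log2pi = 0.5 * np.log(2 * np.pi)
    for it in range(1, max_iter + 1):
        # E-step specialized to k=2, in log space
        la = np.log(lam[0] / sigma[0]) - half_log2pi - 0.5 * ((x - mu[0]) / sigma[0]) ** 2
        lb = np.log(lam[1] / sigma[1]) - half_log2pi - 0.5 * ((x - mu[1]) / sigma[1]) ** 2
        hi = np.maximum(la, lb)
        tot = hi + np.log(np.exp(la - hi) + np.exp(lb - hi))
        loglik = float(tot.sum())
        trace[it - 1] = loglik
        r0 = np.exp(la - tot)  # responsibility of component 1
        # M-step
        n0 = max(float(r0.sum()), 1e-12)
        n1 = max(n - n0, 1e-12)
        lam = np.array([n0 / n, n1 / n])
        r0x = float((r0 * x).sum())
        m0 = r0x / n0
        m1 = (float(x.sum()) - r0x) / n1
        d0 = x - m0
        d1 = x - m1
        v0 = float((r0 * d0 * d0).sum()) / n0
        v1 = (float((d1 * d1).sum()) - float((r0 * d1 * d1).sum())) / n1
        mu = np.array([m0, m1])
        sigma = np.sqrt(np.maximum(np.array([v0, v1]), SIGMA_FLOOR**2))
        if it > 1 and loglik - prev < tol * (1.0 + abs(loglik)):
            converged = True
            break
        prev = loglik
    return lam, mu, sigma, trace[it - 1], converged, it, trace[:it]


def fit_mixture_em(
    x,
    k: int = 2,
    seed: int = 0,
    tol: float = 1e-8,
    max_iter: int = 10_000,
    n_starts: int = 10,
    short_run: int = 200,
) -> MixtureFit:
    """Fit a k-component unequal-variance Gaussian mixture by EM.

    The first start splits the data at the median (lower/upper halves
    seed the two components); the remaining starts split at a random
    quantile and jitter the resulting means. Every start runs for
    ``short_run`` iterations, then the best one continues until the
    log-likelihood improves by less than ``tol`` per iteration (heavily
    overlapping components need thousands of iterations at this
    tolerance, hence the large ``max_iter``). Components are
    relabelled by ascending mean.
    """
    if k not in (1, 2):
        raise ValueError("only k in {1, 2} is supported")
    if k == 1:
        return fit_single_gaussian(x)
    x = _validate(x, 10 * k)
    rng = np.random.default_rng(seed)
    xs = np.sort(x)
    best: tuple | None = None
    for s in range(n_starts):
        q = 0.5 if s == 0 else rng.uniform(0.2, 0.8)
        cut = int(round(q * x.size))
        cut = min(max(cut, 2), x.size - 2)
        lo, hi = xs[:cut], xs[cut:]
        mu0 = np.array([lo.mean(), hi.mean()])
        sigma0 = np.array([max(lo.std(), SIGMA_FLOOR), max(hi.std(), SIGMA_FLOOR)])
        lam0 = np.array([q, 1 - q])
        if s > 0:
            mu0 = mu0 + rng.normal(0, 0.25 * x.std() + 1e-12, size=2)
        res = _em_run(x, lam0, mu0, sigma0, tol, short_run)
        if best is None or res[3] > best[3]:
            best = res
    assert best is not None
    if not best[4]:  # best short run not yet converged: continue it
        lam0, mu0, sigma0 = best[0], best[1], best[2]
        short_trace = best[6]
        res = _em_run(x, lam0, mu0, sigma0, tol, max_iter - short_run)
        best = (*res[:6], np.concatenate([short_trace, res[6]]))
    lam, mu, sigma, loglik, converged, n_iter, trace = best
    if not converged:
        order = np.argsort(mu)
        partial = MixtureFit(
            k=2, lambda_=lam[order], mu=mu[order], sigma=sigma[order],
            loglik=loglik, bic=_bic(loglik, 5, x.size), n=x.size,
            converged=False, n_iter=n_iter, loglik_trace=trace,
        )
        raise MixtureConvergenceError(
            f"EM did not converge in {max_iter} iterations from any of "
            f"{n_starts} starts", partial,
        )
    order = np.argsort(mu)
    return MixtureFit(
        k=2,
        lambda_=lam[order],
        mu=mu[order],
        sigma=sigma[order],
        loglik=loglik,
        bic=_bic(loglik, 5, x.size),
        n=x.size,
        converged=converged,
        n_iter=n_iter,
        loglik_trace=trace,
    )


class MixtureConvergenceError(RuntimeError):
    """EM failed to converge; carries the best partial fit."""

    def __init__(self, msg: str, partial: MixtureFit):
        super().__init__(msg)
        self.partial = partial


def select_model(fit1: MixtureFit, fit2: MixtureFit) -> ModelComparison:
    """Compare single-Gaussian vs mixture fits on the same data.

    Selection is by BIC (lower wins); both BIC and the raw
    log-likelihoods are reported.
    """
    if fit1.n != fit2.n:
        raise ValueError(f"fits are on different data: n={fit1.n} vs n={fit2.n}")
    delta = fit2.bic - fit1.bic
    return ModelComparison(
        loglik_1=fit1.loglik,
        loglik_2=fit2.loglik,
        bic_1=fit1.bic,
        bic_2=fit2.bic,
        delta_bic=delta,
        selected_k=fit2.k if fit2.bic < fit1.bic else fit1.k,
    )


def intersection_threshold(
    lambda_: np.ndarray, mu: np.ndarray, sigma: np.ndarray
) -> float:
    """Crossover point of the two weighted component densities.

    Solves lam1*N(x|mu1,s1) = lam2*N(x|mu2,s2). Taking logs gives a
    quadratic in x (linear when the sigmas are equal). The returned
    root is the crossing where the low-mean component stops dominating
    — i.e. where the log-density difference decreases through zero —
    which is the classification boundary between the components. With
    unequal variances this point can lie slightly outside the interval
    (mu1, mu2); with equal lambdas and sigmas it is exactly the
    midpoint of the means.
    """
    (l1, l2), (m1, m2), (s1, s2) = lambda_, mu, sigma
    if not m1 < m2:
        raise ValueError("component means must satisfy mu1 < mu2")
    rhs = np.log(l1 * s2 / (l2 * s1))
    # h(x) = log(l1 N1) - log(l2 N2) = -a x^2 - b' x - ... ; written as
    # a x^2 + b x + c = 0 below with h(x) = -(a x^2 + b x + c)
    a = 1.0 / (2 * s1**2) - 1.0 / (2 * s2**2)
    b = -m1 / s1**2 + m2 / s2**2
    c = m1**2 / (2 * s1**2) - m2**2 / (2 * s2**2) - rhs
    if abs(a) < 1e-300:
        roots = np.array([-c / b])
    else:
        disc = b * b - 4 * a * c
        if disc <= 0:
            raise ValueError(
                "component densities do not cross; "
                "consider a quantile-based fallback threshold"
            )
        sq = np.sqrt(disc)
        roots = np.array([(-b - sq) / (2 * a), (-b + sq) / (2 * a)])

    def h_prime(x: float) -> float:
        return -(x - m1) / s1**2 + (x - m2) / s2**2

    falling = [r for r in roots if h_prime(r) < 0]
    if not falling:
        raise ValueError(
            "no crossing where the low component stops dominating; "
            "consider a quantile-based fallback threshold"
        )
    return float(falling[0])


def component_intersection(fit: MixtureFit) -> float:
    if fit.k != 2:
        raise ValueError("intersection requires a 2-component fit")
    return intersection_threshold(fit.lambda_, fit.mu, fit.sigma)


def classify_genes(records, threshold: float) -> ComponentSplit:
    """Assign each profiled gene to the low or high component.

    A gene is "low" iff its cpg_oe is strictly below the threshold;
    values exactly at the threshold go to "high". Also reports the
    fraction of CpG-depleted genes (cpg_oe < 1.0).
    """
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    records = list(records)
    if not records:
        raise ValueError("no records to classify")
    assignment = {
        r.gene_id: ("low" if r.cpg_oe < threshold else "high") for r in records
    }
    n_low = sum(1 for v in assignment.values() if v == "low")
    frac_depleted = float(np.mean([r.cpg_oe < 1.0 for r in records]))
    return ComponentSplit(
        threshold=float(threshold),
        assignment=assignment,
        n_low=n_low,
        n_high=len(records) - n_low,
        frac_depleted=frac_depleted,
    )
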