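"""Synthetic data with the statistical structure the pipeline assumes.

The generator produces, from one seed: (i) per-gene CpG_O/E targets
drawn from a two-component Gaussian mixture (defaults are the fitted
seagrass transcriptome parameters: mixing 0.661/0.339, means
0.476/0.650, standard deviations 0.127/0.214, truncated to
(0.05, 2.0)); (ii) transcript sequences realizing those targets via a
first-order Markov chain whose C->G transition probability is tuned so
the expected CpG_O/E of a long sequence equals the target; (iii) GO
annotations where low-CpG genes favour a "constitutive" term pool and
high-CpG genes a "responsive" pool, with configurable odds bias;
(iv) NB counts for a 2 origin x 2 treatment x n replicate design in
which the probability of being origin- or treatment-responsive rises
with the CpG_O/E target on the logit scale. The ground-truth component
labels and expression effects are returned for recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from .io import GeneSeq, SampleDesign

DEFAULT_MIXTURE = {
    "lambda": (0.661, 0.339),
    "mu": (0.476, 0.650),
    "sigma": (0.127, 0.214),
}

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_A, _C, _G, _T = 0, 1, 2, 3


def _logit(p: float) -> float:
    return float(np.log(p / (1 - p)))


# Stage tags keep standalone calls on independent streams derived from
# one seed (sharing default_rng(seed) across stages would reuse the
# same uniforms, silently coupling e.g. responsiveness to component).
_STAGE_TAG = {"targets": 1, "sequences": 2, "annotations": 3, "counts": 4}


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    return np.random.default_rng([_STAGE_TAG[stage], seed])


@dataclass
class SimConfig:
    """Study conditions for the synthetic dataset.

    Defaults emulate a seagrass-like transcriptome: ~41% GC, lognormal
    gene lengths with median 930 bp (clipped to [201, 8000]), the
    fitted CpG_O/E mixture above, moderate NB overdispersion
    (phi = 0.2), and a logit-linear link (intercept -5, slope 3)
    between a gene's CpG_O/E target and its probability of responding
    to origin or treatment; responsive genes carry |log2 effects| of
    about 2.
    """

    n_genes: int = 10_000
    mixture: dict = field(default_factory=lambda: dict(DEFAULT_MIXTURE))
    target_bounds: tuple[float, float] = (0.05, 2.0)
    length_median: float = 930.0
    length_sigma: float = 0.6
    length_bounds: tuple[int, int] = (201, 8000)
    gc: float = 0.41
    de_intercept: float = -5.0
    de_slope: float = 3.0
    effect_mean: float = 2.0  # |log2 fold change| of responsive genes
    effect_sd: float = 0.5
    effect_min: float = 0.5
    phi: float = 0.2
    lib_size_mean: float = 5e5
    lib_size_cv: float = 0.15
    baseline_log_mean: float = float(np.log(30.0))
    baseline_log_sd: float = 1.2
    n_replicates: int = 3
    annotation_bias: float = 3.0
    seed: int = 0

    def base_freqs(self) -> np.ndarray:
        at = (1 - self.gc) / 2
        gc = self.gc / 2
        return np.array([at, gc, gc, at])


def simulate_cpg_targets(cfg: SimConfig, rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Draw per-gene CpG_O/E targets and true component labels."""
    rng = stage_rng(cfg.seed, "targets") if rng is None else rng
    lam = np.asarray(cfg.mixture["lambda"], dtype=float)
    mu = np.asarray(cfg.mixture["mu"], dtype=float)
    sigma = np.asarray(cfg.mixture["sigma"], dtype=float)
    if not np.isclose(lam.sum(), 1.0):
        raise ValueError("mixture proportions must sum to 1")
    comp = rng.choice(lam.size, size=cfg.n_genes, p=lam)
    lo, hi = cfg.target_bounds
    a = (lo - mu[comp]) / sigma[comp]
    b = (hi - mu[comp]) / sigma[comp]
    vals = truncnorm.rvs(a, b, loc=mu[comp], scale=sigma[comp], random_state=rng)
    width = len(str(cfg.n_genes))
    ids = [f"g{i:0{width}d}" for i in range(1, cfg.n_genes + 1)]
    return pd.DataFrame(
        {"gene_id": ids, "target_oe": vals, "true_component": np.where(comp == 0, "low", "high")}
    )


def simulate_lengths(cfg: SimConfig, rng: np.random.Generator) -> np.ndarray:
    raw = rng.lognormal(mean=np.log(cfg.length_median), sigma=cfg.length_sigma, size=cfg.n_genes)
    return np.clip(raw, *cfg.length_bounds).astype(np.int64)


def _refine_cpg_count(row: np.ndarray, target: float, max_passes: int = 8) -> None:
    """Nudge a sequence's realized CpG count to match its target, in place.

    Adjacent-base transpositions preserve the base composition exactly:
    swapping a "GC" pair to "CG" adds one CpG and swapping "CG" to "GC"
    removes one, provided the flanking bases are not C (left) or G
    (right). The desired count solves the O/E formula for n_cpg given
    the realized composition, so after refinement the computed CpG_O/E
    equals the target up to integer rounding.
    """
    l = row.size
    n_c = int((row == _C).sum())
    n_g = int((row == _G).sum())
    if n_c == 0 or n_g == 0 or l < 2:
        return
    want = int(round(target * n_c * n_g * (l - 1) / (l * l)))
    want = min(want, min(n_c, n_g))
    for _ in range(max_passes):
        is_cg = (row[:-1] == _C) & (row[1:] == _G)
        have = int(is_cg.sum())
        delta = want - have
        if delta == 0:
            return
        if delta > 0:
            cand = np.flatnonzero((row[:-1] == _G) & (row[1:] == _C))
        else:
            cand = np.flatnonzero(is_cg)
        left_ok = np.ones(cand.size, dtype=bool)
        inner = cand > 0
        left_ok[inner] = row[cand[inner] - 1] != _C
        right_ok = np.ones(cand.size, dtype=bool)
        inner = cand < l - 2
        right_ok[inner] = row[cand[inner] + 2] != _G
        cand = cand[left_ok & right_ok]
        if cand.size == 0:
            return
        picked = []
        last = -10
        for i in cand:
            if i - last >= 3:
                picked.append(i)
                last = i
            if len(picked) == abs(delta):
                break
        if not picked:
            return
        idx = np.array(picked)
        row[idx], row[idx + 1] = row[idx + 1].copy(), row[idx].copy()


def _markov_sequences(
    targets: np.ndarray,
    lengths: np.ndarray,
    base_freqs: np.ndarray,
    rng: np.random.Generator,
    refine: bool = True,
) -> list[str]:
    """Generate all sequences in lockstep, one position per vector step.

    From any state but C the next base follows ``base_freqs``; from C
    the probability of G is clip(target * pi_G, 0, 0.95) and the
    remaining mass is spread over A/C/T proportionally to their base
    frequencies, which makes the expected observed/expected CpG ratio
    of a long chain approximately the target. With ``refine`` the
    realized CpG count is then tuned to the target by
    composition-preserving adjacent swaps, removing most of the
    finite-length sampling noise around it.
    """
    n = targets.size
    pi_g = base_freqs[_G]
    p_cg = targets * pi_g
    if (p_cg >= 1.0).any():
        raise ValueError("infeasible C->G transition: target_oe * pi_G >= 1")
    p_cg = np.clip(p_cg, 0.0, 0.95)
    other = base_freqs[[_A, _C, _T]]
    rest = (1.0 - p_cg)[:, None] * (other / other.sum())[None, :]
    cond_c = np.empty((n, 4))
    cond_c[:, _A] = rest[:, 0]
    cond_c[:, _C] = rest[:, 1]
    cond_c[:, _G] = p_cg
    cond_c[:, _T] = rest[:, 2]
    cond_c_cum = np.cumsum(cond_c, axis=1)
    base_cum = np.cumsum(base_freqs)
    maxlen = int(lengths.max())
    seq = np.empty((n, maxlen), dtype=np.uint8)
    prev_c = np.zeros(n, dtype=bool)
    for j in range(maxlen):
        u = rng.random(n)
        nxt_iid = (u[:, None] >= base_cum[None, :3]).sum(axis=1)
        nxt_c = (u[:, None] >= cond_c_cum[:, :3]).sum(axis=1)
        col = np.where(prev_c, nxt_c, nxt_iid).astype(np.uint8)
        seq[:, j] = col
        prev_c = col == _C
    out = []
    for i in range(n):
        row = seq[i, : lengths[i]]
        if refine:
            _refine_cpg_count(row, targets[i])
        out.append(_BASES[row].tobytes().decode("ascii"))
    return out


def simulate_sequences(
    targets: pd.DataFrame, cfg: SimConfig, rng: np.random.Generator
) -> list[GeneSeq]:
    lengths = simulate_lengths(cfg, rng)
    seqs = _markov_sequences(
        targets["target_oe"].to_numpy(), lengths, cfg.base_freqs(), rng
    )
    return [GeneSeq(g, s) for g, s in zip(targets["gene_id"], seqs)]


def simulate_sequence(
    target_oe: float, length: int, base_freqs, rng: np.random.Generator
) -> str:
    """Single sequence with the given CpG_O/E target."""
    if not 0.0 <= target_oe <= 2.0:
        raise ValueError("target_oe must lie in [0, 2]")
    if length < 200:
        raise ValueError("length must be >= 200")
    return _markov_sequences(
        np.array([target_oe]), np.array([length]), np.asarray(base_freqs, float), rng
    )[0]


DEFAULT_TERM_POOLS = {
    "constitutive": [
        "protein metabolic process", "cell cycle", "DNA metabolic process",
        "regulation of gene expression", "signaling", "RNA metabolic process",
        "cytoskeleton organization", "transport", "catabolic process",
        "organelle organization",
    ],
    "responsive": [
        "translation", "photosynthesis", "response to stress",
        "response to stimulus", "response to abiotic stimulus",
        "cell wall organization", "lipid metabolic process",
        "carbohydrate metabolic process", "generation of precursor metabolites",
        "secondary metabolic process",
    ],
}


def simulate_annotations(
    true_components,
    term_pools: dict[str, list[str]] | None = None,
    bias: float = 3.0,
    rng: np.random.Generator | None = None,
    mean_terms: float = 1.5,
) -> dict[str, set[str]]:
    """Component-biased GO annotations; every gene gets >= 1 term.

    Low-component genes draw terms from the constitutive pool with
    their odds multiplied by ``bias``; high-component genes likewise
    for the responsive pool. ``bias = 1`` makes term choice independent
    of the component.
    """
    if bias < 1:
        raise ValueError("bias must be >= 1")
    pools = DEFAULT_TERM_POOLS if term_pools is None else term_pools
    cons, resp = pools["constitutive"], pools["responsive"]
    if not cons or not resp:
        raise ValueError("term pools must be non-empty")
    rng = np.random.default_rng(0) if rng is None else rng
    terms = np.array(cons + resp)
    n_cons = len(cons)
    w_low = np.concatenate([np.full(n_cons, bias), np.ones(len(resp))])
    w_high = np.concatenate([np.ones(n_cons), np.full(len(resp), bias)])
    w_low /= w_low.sum()
    w_high /= w_high.sum()
    out: dict[str, set[str]] = {}
    comp = true_components if isinstance(true_components, dict) else dict(
        zip(true_components["gene_id"], true_components["true_component"])
    )
    for gene, c in comp.items():
        k = 1 + rng.poisson(mean_terms - 1.0)
        k = min(k, terms.size)
        p = w_low if c == "low" else w_high
        chosen = rng.choice(terms, size=k, replace=False, p=p)
        out[gene] = set(chosen.tolist())
    return out


def default_design(n_replicates: int = 3) -> list[SampleDesign]:
    design = []
    for origin in ("cold", "warm"):
        for treatment in ("control", "heated"):
            for r in range(1, n_replicates + 1):
                design.append(SampleDesign(f"{origin}_{treatment}_{r}", origin, treatment, r))
    return design


def simulate_counts(
    targets: pd.DataFrame, cfg: SimConfig, rng: np.random.Generator | None = None
) -> tuple[pd.DataFrame, list[SampleDesign], pd.DataFrame]:
    """NB counts with CpG-linked responsiveness; returns the truth table.

    A gene is origin-responsive with probability
    sigmoid(intercept + slope * target_oe) and, independently,
    treatment-responsive with the same law. Responsive genes carry a
    random-sign log2 effect; counts are gamma-Poisson (NB) with
    dispersion ``cfg.phi`` around baseline * library factor * 2^effect.
    """
    rng = stage_rng(cfg.seed, "counts") if rng is None else rng
    if cfg.n_replicates < 2:
        raise ValueError("need >= 2 replicates per design cell")
    design = default_design(cfg.n_replicates)
    n = len(targets)
    t = targets["target_oe"].to_numpy()
    p_resp = 1.0 / (1.0 + np.exp(-(cfg.de_intercept + cfg.de_slope * t)))
    origin_resp = rng.random(n) < p_resp
    treat_resp = rng.random(n) < p_resp

    def effects(mask):
        e = np.zeros(n)
        k = int(mask.sum())
        mag = np.maximum(rng.normal(cfg.effect_mean, cfg.effect_sd, size=k), cfg.effect_min)
        e[mask] = mag * rng.choice([-1.0, 1.0], size=k)
        return e

    origin_eff = effects(origin_resp)
    treat_eff = effects(treat_resp)
    baseline = rng.lognormal(cfg.baseline_log_mean, cfg.baseline_log_sd, size=n)
    lib_sigma = np.sqrt(np.log(1 + cfg.lib_size_cv**2))
    lib = rng.lognormal(np.log(cfg.lib_size_mean) - lib_sigma**2 / 2, lib_sigma, size=len(design))
    lib_factor = lib / lib.mean()
    counts = np.empty((n, len(design)), dtype=np.int64)
    for j, d in enumerate(design):
        log2_shift = origin_eff * (d.origin == "warm") + treat_eff * (d.treatment == "heated")
        mean = baseline * lib_factor[j] * np.exp2(log2_shift)
        if cfg.phi > 0:
            lam = rng.gamma(shape=1.0 / cfg.phi, scale=mean * cfg.phi)
        else:
            lam = mean
        counts[:, j] = rng.poisson(lam)
    counts_df = pd.DataFrame(
        counts, index=targets["gene_id"].to_numpy(), columns=[d.sample_id for d in design]
    )
    counts_df.index.name = "gene_id"
    truth = targets.assign(
        origin_responsive=origin_resp,
        treatment_responsive=treat_resp,
        origin_effect=origin_eff,
        treatment_effect=treat_eff,
    )
    return counts_df, design, truth


def simulate_dataset(cfg: SimConfig) -> dict:
    """Full synthetic study from one seed.

    Returns sequences, targets/truth, annotations, counts and design
    in the same shapes the readers produce from disk.
    """
    targets = simulate_cpg_targets(cfg, stage_rng(cfg.seed, "targets"))
    seqs = simulate_sequences(targets, cfg, stage_rng(cfg.seed, "sequences"))
    annotations = simulate_annotations(
        targets, bias=cfg.annotation_bias, rng=stage_rng(cfg.seed, "annotations")
    )
    counts, design, truth = simulate_counts(targets, cfg, stage_rng(cfg.seed, "counts"))
    return {
        "sequences": seqs,
        "targets": targets,
        "annotations": annotations,
        "counts": counts,
        "design": design,
        "truth": truth,
    }


def slim_ontology_for_pools(term_pools: dict[str, list[str]] | None = None):
    """Trivial ontology for simulated annotations: every pool term
    is_a its pool root; the slim list is the pool terms themselves."""
    pools = DEFAULT_TERM_POOLS if term_pools is None else term_pools
    edges = []
    for root, terms in pools.items():
        root_term = f"{root} process"
        edges.extend((t, root_term) for t in terms)
    slim = {t for terms in pools.values() for t in terms}
    return edges, slim
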