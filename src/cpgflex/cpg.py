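"""Per-gene CpG observed/expected ratio.

The normalized CpG content of a transcript,

    CpG_O/E = n_CpG / (n_C * n_G) * l^2 / (l - 1),

is a proxy for germline gene-body methylation: methylated cytosines
deaminate to thymine over evolutionary time, so historically
hypermethylated genes are depleted in CpG dinucleotides and show
CpG_O/E well below 1, while hypomethylated genes stay near 1. The
``l^2/(l-1)`` factor corrects for sequence length.

Counting is strand-aware (transcripts are assumed oriented 5'->3') and
overlapping: "CGCG" contains two CpG sites. Ambiguous IUPAC bases (N,
R, Y, ...) are excluded from every count and break dinucleotide
adjacency, so "CNG" contains no CpG.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .io import GeneSeq

logger = logging.getLogger(__name__)

_C = ord("C")
_G = ord("G")
_ACGT = frozenset(b"ACGT")


@dataclass(frozen=True)
class CpGRecord:
    """Dinucleotide counts and the CpG_O/E statistic for one gene.

    ``l`` is the number of unambiguous (A/C/G/T) bases; ``cpg_oe`` is
    NaN when the ratio is undefined (no C or no G in the sequence).
    """

    gene_id: str
    n_cpg: int
    n_c: int
    n_g: int
    l: int
    cpg_oe: float


def count_dinucleotides(seq: str) -> tuple[int, int, int, int]:
    """Count overlapping CG dinucleotides and C/G/base totals.

    Returns ``(n_cpg, n_c, n_g, l)`` where ``l`` counts only A/C/G/T
    bases. A CG pair is counted only when C and G are immediately
    adjacent in the input; any intervening ambiguous base breaks the
    pair.
    """
    a = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    if a.size == 0:
        return 0, 0, 0, 0
    is_c = a == _C
    is_g = a == _G
    n_c = int(is_c.sum())
    n_g = int(is_g.sum())
    l = n_c + n_g + int((a == ord("A")).sum()) + int((a == ord("T")).sum())
    n_cpg = int((is_c[:-1] & is_g[1:]).sum()) if a.size > 1 else 0
    return n_cpg, n_c, n_g, l


def compute_cpg_oe(n_cpg: int, n_c: int, n_g: int, l: int) -> float:
    """Length-corrected observed/expected CpG ratio.

    Returns NaN when the sequence has no C or no G (the expected count
    is zero and the ratio is undefined; such genes are excluded
    downstream). Raises for degenerate sequences shorter than two
    counted bases, where the length correction itself is undefined.
    """
    if l < 2:
        raise ValueError(f"degenerate gene: only {l} unambiguous bases (need >= 2)")
    if n_c == 0 or n_g == 0:
        return float("nan")
    return n_cpg / (n_c * n_g) * l * l / (l - 1)


def profile_transcriptome(
    seqs: Sequence[GeneSeq],
    min_length: int = 201,
    max_oe: float | None = None,
) -> tuple[list[CpGRecord], dict[str, str]]:
    """Compute CpG_O/E for every gene, applying the profiling filters.

    A gene is kept when it has at least ``min_length`` unambiguous
    bases, a defined CpG_O/E, and (if ``max_oe`` is set) a ratio not
    exceeding it. Returns the kept records plus a mapping of excluded
    gene_id -> reason.
    """
    if not seqs:
        raise ValueError("no sequences to profile")
    records: list[CpGRecord] = []
    excluded: dict[str, str] = {}
    for gs in seqs:
        n_cpg, n_c, n_g, l = count_dinucleotides(gs.sequence)
        if l < max(min_length, 2):
            excluded[gs.gene_id] = f"short: l={l} < {min_length}"
            continue
        oe = compute_cpg_oe(n_cpg, n_c, n_g, l)
        if np.isnan(oe):
            excluded[gs.gene_id] = "undefined: no C or no G"
            continue
        if max_oe is not None and oe > max_oe:
            excluded[gs.gene_id] = f"cpg_oe={oe:.4g} > max_oe={max_oe:.4g}"
            continue
        records.append(CpGRecord(gs.gene_id, n_cpg, n_c, n_g, l, oe))
    if not records:
        raise ValueError("all genes excluded by profiling filters")
    if excluded:
        logger.info("profile_transcriptome: excluded %d of %d genes", len(excluded), len(seqs))
    return records, excluded


def records_to_frame(records: Iterable[CpGRecord]):
    """CpG records as a DataFrame (gene_id, l, n_cpg, n_c, n_g, cpg_oe)."""
    import pandas as pd

    return pd.DataFrame(
        [(r.gene_id, r.l, r.n_cpg, r.n_c, r.n_g, r.cpg_oe) for r in records],
        columns=["gene_id", "l", "n_cpg", "n_c", "n_g", "cpg_oe"],
    )
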