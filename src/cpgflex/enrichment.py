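"""GO-slim mapping and low/high-component enrichment.

Gene annotations are collapsed onto a configurable slim set of
high-level biological-process terms by ancestor closure over the
ontology's is_a edges (a term maps to every slim term among its
ancestors, itself included). Per-term CpG_O/E summaries and Fisher
exact enrichment of each component against the remaining profiled,
annotated genes follow, with BH correction across terms within each
component.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .mixture import ComponentSplit
from .stats import bh_fdr, fisher_exact_2x2

logger = logging.getLogger(__name__)

COMPONENTS = ("low", "high")


@dataclass
class SlimAnnotation:
    """Per-gene slim biological-process terms.

    ``unassigned`` lists genes whose terms reach no slim term through
    the ontology.
    """

    gene_terms: dict[str, set[str]]
    unassigned: list[str]


def significance_stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def map_to_slim(
    annotations: dict[str, set[str]],
    is_a_edges: list[tuple[str, str]],
    slim_terms: set[str],
) -> SlimAnnotation:
    """Collapse annotations onto the slim set by is_a ancestor closure."""
    if not slim_terms:
        raise ValueError("slim term list is empty")
    g = nx.DiGraph()
    g.add_edges_from(is_a_edges)  # child -> parent
    if not nx.is_directed_acyclic_graph(g):
        cycle = nx.find_cycle(g)
        raise ValueError(f"is_a graph contains a cycle through {cycle[0][0]!r}")
    cache: dict[str, frozenset[str]] = {}

    def slim_of(term: str) -> frozenset[str]:
        hit = cache.get(term)
        if hit is None:
            ancestors = {term}
            if term in g:
                ancestors |= nx.descendants(g, term)  # parents lie downstream
            hit = frozenset(ancestors & slim_terms)
            cache[term] = hit
        return hit

    gene_terms: dict[str, set[str]] = {}
    unassigned: list[str] = []
    for gene, terms in annotations.items():
        mapped: set[str] = set()
        for t in terms:
            mapped |= slim_of(t)
        if mapped:
            gene_terms[gene] = mapped
        else:
            unassigned.append(gene)
    if unassigned:
        logger.info("map_to_slim: %d genes reach no slim term", len(unassigned))
    return SlimAnnotation(gene_terms=gene_terms, unassigned=sorted(unassigned))


def category_cpg_summary(slim: SlimAnnotation, records) -> pd.DataFrame:
    """Mean CpG_O/E (± SE) per slim term.

    Genes carrying several terms contribute to each; single-gene terms
    report SE = 0 with a flag.
    """
    oe = {r.gene_id: r.cpg_oe for r in records}
    rows = []
    terms = sorted({t for ts in slim.gene_terms.values() for t in ts})
    for term in terms:
        vals = np.array(
            [oe[g] for g, ts in slim.gene_terms.items() if term in ts and g in oe]
        )
        if vals.size == 0:
            logger.info("category_cpg_summary: term %r has no profiled genes", term)
            continue
        se = float(vals.std(ddof=1) / np.sqrt(vals.size)) if vals.size > 1 else 0.0
        rows.append(
            {
                "term": term,
                "n_genes": int(vals.size),
                "mean_cpg_oe": float(vals.mean()),
                "se_cpg_oe": se,
                "single_gene": vals.size == 1,
            }
        )
    return pd.DataFrame(rows, columns=["term", "n_genes", "mean_cpg_oe", "se_cpg_oe", "single_gene"])


def fisher_enrichment(split: ComponentSplit, slim: SlimAnnotation) -> pd.DataFrame:
    """Per-term Fisher enrichment of each component vs the background.

    The background is every classified gene with at least one slim
    term. For each term and component the 2x2 table contrasts the
    component's genes against the remaining background genes
    (term membership x component membership); BH correction is applied
    across terms within each component. Direction follows the odds
    ratio: > 1 means the term is over-represented in that component.
    """
    shared = [g for g in slim.gene_terms if g in split.assignment]
    if not shared:
        raise ValueError("classification and slim annotation share no genes")
    terms = sorted({t for g in shared for t in slim.gene_terms[g]})
    comp_of = split.assignment
    n_bg = len(shared)
    term_genes = {t: {g for g in shared if t in slim.gene_terms[g]} for t in terms}
    rows = []
    for component in COMPONENTS:
        comp_genes = {g for g in shared if comp_of[g] == component}
        n_comp = len(comp_genes)
        ps = []
        for term in terms:
            in_term = term_genes[term]
            a = len(in_term & comp_genes)
            b = n_comp - a
            c = len(in_term) - a
            d = (n_bg - n_comp) - c
            res = fisher_exact_2x2(a, b, c, d)
            ps.append(res.p_value)
            if np.isnan(res.odds_ratio):
                direction = "undetermined"
            elif res.odds_ratio > 1:
                direction = f"{component}-enriched"
            else:
                other = "high" if component == "low" else "low"
                direction = f"{other}-enriched"
            rows.append(
                {
                    "term": term,
                    "component": component,
                    "n_in_component": a,
                    "n_component": n_comp,
                    "n_in_background": len(in_term),
                    "n_background": n_bg,
                    "odds_ratio": res.odds_ratio,
                    "p": res.p_value,
                    "direction": direction,
                }
            )
        fdrs = bh_fdr(ps)
        for i, term in enumerate(terms):
            rows[-len(terms) + i]["fdr"] = float(fdrs[i])
    df = pd.DataFrame(rows)
    df["stars"] = df["fdr"].map(significance_stars)
    return df
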