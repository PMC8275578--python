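"""Readers and writers for the pipeline's external formats.

Sequences come in as plain FASTA (one record per gene; the gene id is
the first whitespace-delimited token of the header). Counts, sample
design, GO annotations, is_a edges and slim term lists are tab-separated
text. All numeric table output is serialized with 6 significant digits
so repeated runs diff cleanly; the JSON run summary keeps full doubles.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import NamedTuple

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

IUPAC_DNA = frozenset("ACGTRYSWKMBDHVN")

ORIGINS = ("cold", "warm")
TREATMENTS = ("control", "heated")


class GeneSeq(NamedTuple):
    """One gene: unique id plus an uppercase IUPAC DNA sequence."""

    gene_id: str
    sequence: str


class SampleDesign(NamedTuple):
    sample_id: str
    origin: str
    treatment: str
    replicate: int


def read_fasta(path: str | Path) -> list[GeneSeq]:
    """Read gene sequences from FASTA, order preserved.

    Raises on duplicate gene ids, empty files, and characters outside
    the IUPAC DNA alphabet (reported with record and position).
    """
    out: list[GeneSeq] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        gene_id = rec.id
        if not gene_id:
            raise ValueError(f"{path}: record with empty id")
        if gene_id in seen:
            raise ValueError(f"{path}: duplicate gene id {gene_id!r}")
        seen.add(gene_id)
        seq = str(rec.seq).upper()
        if not seq:
            raise ValueError(f"{path}: record {gene_id!r} has empty sequence")
        for i, ch in enumerate(seq):
            if ch not in IUPAC_DNA:
                raise ValueError(
                    f"{path}: record {gene_id!r} has non-IUPAC character {ch!r} at position {i + 1}"
                )
        out.append(GeneSeq(gene_id, seq))
    if not out:
        raise ValueError(f"{path}: no FASTA records found")
    return out


def write_fasta(seqs: list[GeneSeq], path: str | Path, width: int = 70) -> None:
    records = [
        SeqRecord(Seq(s.sequence), id=s.gene_id, description="") for s in seqs
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


def read_design(path: str | Path) -> list[SampleDesign]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "origin", "treatment", "replicate"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: design table missing columns {sorted(missing)}")
    if df["sample_id"].duplicated().any():
        dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise ValueError(f"{path}: duplicate sample_id {dup!r}")
    rows = []
    for _, r in df.iterrows():
        if r["origin"] not in ORIGINS:
            raise ValueError(f"{path}: origin {r['origin']!r} not in {ORIGINS}")
        if r["treatment"] not in TREATMENTS:
            raise ValueError(f"{path}: treatment {r['treatment']!r} not in {TREATMENTS}")
        rep = int(r["replicate"])
        if rep < 1:
            raise ValueError(f"{path}: replicate must be a positive integer")
        rows.append(SampleDesign(r["sample_id"], r["origin"], r["treatment"], rep))
    return rows


def read_counts(
    counts_path: str | Path, design_path: str | Path
) -> tuple[pd.DataFrame, list[SampleDesign]]:
    """Read a gene x sample count matrix and its matching design table.

    Every counts column must appear in the design and vice versa;
    counts must be non-negative integers (a value like "3.7" is an
    error, not silently truncated).
    """
    raw = pd.read_csv(counts_path, sep="\t", index_col=0)
    raw.index = raw.index.astype(str)
    design = read_design(design_path)
    design_ids = {d.sample_id for d in design}
    matrix_ids = set(map(str, raw.columns))
    for sid in raw.columns:
        if str(sid) not in design_ids:
            raise ValueError(f"sample {sid!r} in counts has no design row")
    for sid in design_ids:
        if sid not in matrix_ids:
            raise ValueError(f"sample {sid!r} in design is missing from counts")
    vals = raw.to_numpy()
    if not np.isfinite(vals).all():
        raise ValueError("counts contain non-finite values")
    if (vals < 0).any():
        raise ValueError("counts contain negative values")
    if not np.allclose(vals, np.round(vals)):
        bad = np.argwhere(~np.isclose(vals, np.round(vals)))[0]
        raise ValueError(
            f"non-integer count {vals[tuple(bad)]!r} for gene "
            f"{raw.index[bad[0]]!r}, sample {raw.columns[bad[1]]!r}"
        )
    counts = raw.round().astype(np.int64)
    counts.columns = counts.columns.astype(str)
    return counts, design


def read_annotations(path: str | Path) -> dict[str, set[str]]:
    """gene_id<TAB>go_term pairs, one per line -> gene -> set of terms."""
    annot: dict[str, set[str]] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{ln}: expected gene_id<TAB>term")
            gene, term = parts
            annot.setdefault(gene, set()).add(term)
    if not annot:
        raise ValueError(f"{path}: no annotations found")
    return annot


def read_ontology_edges(path: str | Path) -> list[tuple[str, str]]:
    """child<TAB>parent is_a edges."""
    edges = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{ln}: expected child<TAB>parent")
            edges.append((parts[0], parts[1]))
    return edges


def read_slim_terms(path: str | Path) -> set[str]:
    with open(path) as fh:
        terms = {line.strip() for line in fh if line.strip() and not line.startswith("#")}
    if not terms:
        raise ValueError(f"{path}: empty slim term list")
    return terms


def format_table(df: pd.DataFrame, sig: int = 6) -> pd.DataFrame:
    """Render float columns to ``sig`` significant digits (as strings)."""
    out = df.copy()
    for col in out.columns:
        if pd.api.types.is_float_dtype(out[col]):
            out[col] = out[col].map(lambda v: "NA" if pd.isna(v) else f"{v:.{sig}g}")
    return out


def write_tsv(df: pd.DataFrame, path: str | Path, sig: int = 6) -> None:
    format_table(df, sig=sig).to_csv(path, sep="\t", index=False)


def write_json(obj, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, allow_nan=True)
        fh.write("\n")
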