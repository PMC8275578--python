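"""Pipeline orchestration: chain the stages and write run artifacts.

A run is described by a YAML/dict config naming either on-disk inputs
or a ``simulate`` block, plus stage parameters and a seed. Artifacts
are TSV tables (6 significant digits) and a JSON run summary with full
double precision; a plain-text log records stage timings. The same
config and seed reproduce byte-identical numeric outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cpg as cpg_mod
from . import diffexpr, enrichment, flexibility, io, mixture, simulate

logger = logging.getLogger(__name__)

ALL_STAGES = ("cpg", "mixture", "classify", "enrich", "de", "flexibility")
DEFAULT_PARAMS = {
    "min_length": 201,
    "max_oe": None,
    "alpha": 0.05,
    "n_bins_frequency": 25,
    "n_bins_magnitude": 12,
    "contrasts": list(diffexpr.CONTRAST_NAMES),
}


class PipelineError(RuntimeError):
    """Stage failure; carries the stage name."""

    def __init__(self, stage: str, msg: str):
        super().__init__(f"[{stage}] {msg}")
        self.stage = stage


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a YAML mapping")
    return cfg


def _result(tr) -> dict | None:
    if tr is None:
        return None
    d = dataclasses.asdict(tr)
    return {k: v for k, v in d.items() if v is not None}


def _preflight(cfg: dict, stages: list[str]) -> None:
    if "simulate" in cfg:
        return
    inputs = cfg.get("inputs", {})
    needed = {"cpg": ["fasta"], "mixture": ["fasta"], "classify": ["fasta"]}
    needed["enrich"] = ["fasta", "annotations", "ontology", "slim_terms"]
    needed["de"] = ["counts", "design"]
    needed["flexibility"] = ["fasta", "counts", "design"]
    for stage in stages:
        for key in needed.get(stage, []):
            if key not in inputs:
                raise PipelineError(
                    "preflight", f"stage {stage!r} requires input {key!r} in config"
                )
            if not Path(inputs[key]).exists():
                raise PipelineError(
                    "preflight", f"input {key!r} not found: {inputs[key]}"
                )


def run_pipeline(config: dict | str | Path, output_dir: str | Path | None = None) -> dict:
    """Run the configured stages; returns the run summary dict."""
    if not isinstance(config, dict):
        config = load_config(config)
    outdir = Path(output_dir or config.get("output_dir", "cpgflex_out"))
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    params = {**DEFAULT_PARAMS, **config.get("params", {})}
    stages = list(config.get("stages", ALL_STAGES))
    _preflight(config, stages)

    log_path = outdir / "run.log"
    log_fh = open(log_path, "w")
    summary: dict = {"seed": seed, "params": {k: v for k, v in params.items()}}
    t_start = time.perf_counter()

    def stamp(stage: str, t0: float) -> None:
        log_fh.write(f"{stage}: {time.perf_counter() - t0:.2f}s\n")
        log_fh.flush()

    try:
        inputs = dict(config.get("inputs", {}))
        sim_truth = None
        if "simulate" in config:
            t0 = time.perf_counter()
            sim_block = dict(config["simulate"] or {})
            sim_block.setdefault("seed", seed)
            sim_cfg = simulate.SimConfig(**sim_block)
            data = simulate.simulate_dataset(sim_cfg)
            indir = outdir / "inputs"
            indir.mkdir(exist_ok=True)
            io.write_fasta(data["sequences"], indir / "sequences.fasta")
            with open(indir / "annotations.tsv", "w") as fh:
                for g in sorted(data["annotations"]):
                    for t in sorted(data["annotations"][g]):
                        fh.write(f"{g}\t{t}\n")
            edges, slim = simulate.slim_ontology_for_pools()
            with open(indir / "ontology.tsv", "w") as fh:
                for c, p in edges:
                    fh.write(f"{c}\t{p}\n")
            with open(indir / "slim_terms.tsv", "w") as fh:
                for t in sorted(slim):
                    fh.write(t + "\n")
            counts_out = data["counts"].reset_index()
            counts_out.to_csv(indir / "counts.tsv", sep="\t", index=False)
            pd.DataFrame(data["design"]).to_csv(indir / "design.tsv", sep="\t", index=False)
            io.write_tsv(data["truth"], indir / "truth.tsv")
            inputs = {
                "fasta": indir / "sequences.fasta",
                "annotations": indir / "annotations.tsv",
                "ontology": indir / "ontology.tsv",
                "slim_terms": indir / "slim_terms.tsv",
                "counts": indir / "counts.tsv",
                "design": indir / "design.tsv",
            }
            sim_truth = data["truth"]
            summary["simulate"] = {"n_genes": sim_cfg.n_genes, "seed": sim_cfg.seed}
            stamp("simulate", t0)

        records = None
        split = None
        if "cpg" in stages:
            t0 = time.perf_counter()
            try:
                seqs = io.read_fasta(inputs["fasta"])
                records, excluded = cpg_mod.profile_transcriptome(
                    seqs, min_length=params["min_length"], max_oe=params["max_oe"]
                )
            except Exception as e:
                raise PipelineError("cpg", str(e)) from e
            cpg_df = cpg_mod.records_to_frame(records)
            io.write_tsv(cpg_df, outdir / "cpg_profile.tsv")
            if excluded:
                pd.DataFrame(
                    sorted(excluded.items()), columns=["gene_id", "excluded_reason"]
                ).to_csv(outdir / "cpg_excluded.tsv", sep="\t", index=False)
            summary["cpg"] = {"n_profiled": len(records), "n_excluded": len(excluded)}
            stamp("cpg", t0)

        fit2 = None
        if "mixture" in stages:
            t0 = time.perf_counter()
            if records is None:
                raise PipelineError("mixture", "cpg stage must run first")
            try:
                x = np.array([r.cpg_oe for r in records])
                fit1 = mixture.fit_single_gaussian(x)
                fit2 = mixture.fit_mixture_em(x, k=2, seed=seed)
                comparison = mixture.select_model(fit1, fit2)
            except Exception as e:
                raise PipelineError("mixture", str(e)) from e
            report = pd.DataFrame(
                {
                    "component": [1, 2],
                    "lambda": fit2.lambda_,
                    "mu": fit2.mu,
                    "sigma": fit2.sigma,
                    "loglik_k1": fit1.loglik,
                    "loglik_k2": fit2.loglik,
                    "bic_k1": fit1.bic,
                    "bic_k2": fit2.bic,
                }
            )
            io.write_tsv(report, outdir / "mixture_report.tsv")
            summary["mixture"] = {
                "lambda": fit2.lambda_.tolist(),
                "mu": fit2.mu.tolist(),
                "sigma": fit2.sigma.tolist(),
                "loglik_k1": fit1.loglik,
                "loglik_k2": fit2.loglik,
                "bic_k1": fit1.bic,
                "bic_k2": fit2.bic,
                "selected_k": comparison.selected_k,
                "n_iter": fit2.n_iter,
            }
            stamp("mixture", t0)

        if "classify" in stages:
            t0 = time.perf_counter()
            if fit2 is None or records is None:
                raise PipelineError("classify", "mixture stage must run first")
            try:
                threshold = mixture.component_intersection(fit2)
                split = mixture.classify_genes(records, threshold)
            except Exception as e:
                raise PipelineError("classify", str(e)) from e
            cls = pd.DataFrame(
                {
                    "gene_id": [r.gene_id for r in records],
                    "cpg_oe": [r.cpg_oe for r in records],
                    "component": [split.assignment[r.gene_id] for r in records],
                }
            )
            io.write_tsv(cls, outdir / "classification.tsv")
            summary["classify"] = {
                "threshold": split.threshold,
                "n_low": split.n_low,
                "n_high": split.n_high,
                "frac_cpg_depleted": split.frac_depleted,
            }
            stamp("classify", t0)

        if "enrich" in stages:
            t0 = time.perf_counter()
            if split is None or records is None:
                raise PipelineError("enrich", "classify stage must run first")
            try:
                annot = io.read_annotations(inputs["annotations"])
                edges = io.read_ontology_edges(inputs["ontology"])
                slim_terms = io.read_slim_terms(inputs["slim_terms"])
                slim = enrichment.map_to_slim(annot, edges, slim_terms)
                cat = enrichment.category_cpg_summary(slim, records)
                enr = enrichment.fisher_enrichment(split, slim)
            except Exception as e:
                raise PipelineError("enrich", str(e)) from e
            io.write_tsv(cat, outdir / "category_cpg_summary.tsv")
            io.write_tsv(enr, outdir / "enrichment.tsv")
            sig = enr[enr["fdr"] < 0.05]
            summary["enrich"] = {
                "n_terms": int(enr["term"].nunique()),
                "n_unassigned_genes": len(slim.unassigned),
                "n_significant": int(len(sig)),
                "significant": {
                    f"{r.term}|{r.component}": r.direction for r in sig.itertuples()
                },
            }
            stamp("enrich", t0)

        de_tables: dict[str, pd.DataFrame] = {}
        if "de" in stages:
            t0 = time.perf_counter()
            try:
                counts, design = io.read_counts(inputs["counts"], inputs["design"])
                for name in params["contrasts"]:
                    de_tables[name] = diffexpr.run_contrast(
                        counts, design, name, alpha=params["alpha"]
                    )
                    io.write_tsv(de_tables[name], outdir / f"de_{name}.tsv")
            except Exception as e:
                raise PipelineError("de", str(e)) from e
            summary["de"] = diffexpr.summarize_contrasts(de_tables)
            stamp("de", t0)

        if "flexibility" in stages:
            t0 = time.perf_counter()
            if records is None or not de_tables:
                raise PipelineError("flexibility", "cpg and de stages must run first")
            try:
                cpg_df = cpg_mod.records_to_frame(records)
                flex_summary = {}
                freq_tables = {}
                for name, de in de_tables.items():
                    rep = flexibility.flexibility_report(
                        cpg_df,
                        de,
                        name,
                        split=split,
                        n_bins_frequency=params["n_bins_frequency"],
                        n_bins_magnitude=params["n_bins_magnitude"],
                    )
                    io.write_tsv(rep.frequency_bins, outdir / f"bins_{name}_frequency.tsv")
                    io.write_tsv(rep.magnitude_bins, outdir / f"bins_{name}_magnitude.tsv")
                    freq_tables[name] = rep.frequency_bins
                    flex_summary[name] = {
                        "frequency_pearson": _result(rep.frequency_corr),
                        "magnitude_pearson": _result(rep.magnitude_pearson),
                        "magnitude_spearman": _result(rep.magnitude_spearman),
                        "magnitude_anova": _result(rep.magnitude_anova),
                        "component": _result(rep.component) if rep.component else None,
                        "notes": rep.notes,
                    }
                if {"treatment_cold", "treatment_warm"} <= freq_tables.keys():
                    sa, sb, ratio = flexibility.population_slopes(
                        freq_tables["treatment_cold"], freq_tables["treatment_warm"]
                    )
                    flex_summary["population_slopes"] = {
                        "slope_cold": sa,
                        "slope_warm": sb,
                        "ratio_cold_over_warm": ratio,
                    }
            except Exception as e:
                raise PipelineError("flexibility", str(e)) from e
            summary["flexibility"] = flex_summary
            stamp("flexibility", t0)

        if sim_truth is not None and split is not None:
            truth_comp = dict(zip(sim_truth["gene_id"], sim_truth["true_component"]))
            shared = [g for g in split.assignment if g in truth_comp]
            acc = float(
                np.mean([split.assignment[g] == truth_comp[g] for g in shared])
            )
            summary["classification_accuracy_vs_truth"] = acc

        io.write_json(summary, outdir / "summary.json")
        log_fh.write(f"total: {time.perf_counter() - t_start:.2f}s\n")
        return summary
    except PipelineError as e:
        log_fh.write(f"FAILED at stage {e.stage}: {e}\n")
        raise
    finally:
        log_fh.close()
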