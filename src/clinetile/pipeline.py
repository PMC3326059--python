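"""Configuration-driven end-to-end orchestration of the synthetic pipeline.

Stage order is fixed: simulate -> annotate -> preprocess -> teststats ->
call -> overlap -> enrich -> cline. Every stage writes its outputs as TSV
(or JSON) under the output directory and the run ends with a manifest
listing parameters, per-stage seeds and the sha256 checksum of every file,
so a rerun with the same config is byte-identical.
"""

from __future__ import annotations

import copy
import hashlib
import json
import os
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import clinal_stats, enrichment, preprocessing, probewise_stats, region_calling
from . import io as ctio
from . import probe_annotation, synthetic_data
from .annotation import GenomeAnnotation

DEFAULT_CONFIG = {
    "seed": 1,
    "genome": {"n_chromosomes": 2, "chrom_length": 200_000, "n_genes": 80,
               "exons_per_gene": 3, "gene_length_range": [1500, 3000],
               "min_intergenic_gap": 300},
    "probes": {"length": 25, "step": 40},
    "design": {"replicates": 5, "stages": ["L2", "L3"]},
    "effects": {"de_gene_fraction": 0.10, "log2_fold_change": 2.0,
                "probe_affinity_sd": 0.7, "background_trend_amplitude": 50.0,
                "replicate_noise_sd": 0.5, "noise_prior_df": 4.0},
    "preprocessing": {"half_window": 500, "percentile": 5.0, "loess_span": 0.3},
    "thresholds": {"short_p": 1e-5, "medium_p": 0.01, "medium_flank": 1,
                   "long_p": 0.1, "long_halfwidth": 10, "gaussian_variance": 5.0},
    "enrichment": {"n_categories": 40, "size_range": [5, 20],
                   "n_permutations": 200, "method": "normal"},
    "clinal": {"n_populations": 15, "slope": 0.05, "intercept": 3.0,
               "noise_sd": 0.1, "outlier_index": 7, "outlier_shift": 1.0},
}


def load_config(path: Optional[str] = None) -> dict:
    """Merge a YAML config file over the defaults (shallow per section)."""
    config = copy.deepcopy(DEFAULT_CONFIG)
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        for key, value in user.items():
            if isinstance(value, dict) and isinstance(config.get(key), dict):
                config[key].update(value)
            else:
                config[key] = value
    validate_config(config)
    return config

def validate_config(config: dict) -> None:
    for section in DEFAULT_CONFIG:
        if section not in config:
            raise ValueError(f"config missing section {section!r}")
    inputs = config.get("inputs", {})
    for name, path in inputs.items():
        if not os.path.exists(path):
            raise ValueError(f"input file for {name!r} does not exist: {path}")
    # construct the parameter objects early so bad values fail before any work
    g = config["genome"]
    synthetic_data.GenomeSpec(
        n_chromosomes=g["n_chromosomes"], chrom_length=g["chrom_length"],
        n_genes=g["n_genes"], exons_per_gene=g["exons_per_gene"],
        gene_length_range=tuple(g["gene_length_range"]),
        min_intergenic_gap=g.get("min_intergenic_gap", 300),
    )
    synthetic_data.EffectSpec(seed=0, **config["effects"])
    region_calling.ScenarioThresholds(**config["thresholds"])


def generate_categories(gene_ids, n_categories: int, size_range, seed: int) -> dict:
    """Random gene categories over the synthetic gene universe (GMT-style)."""
    rng = np.random.default_rng(seed)
    gene_ids = list(gene_ids)
    lo, hi = size_range
    hi = min(hi, max(1, len(gene_ids) - 1))
    lo = min(lo, hi)
    return {
        f"cat{i + 1:03d}": sorted(
            rng.choice(gene_ids, size=int(rng.integers(lo, hi + 1)), replace=False)
        )
        for i in range(n_categories)
    }


def _json_default(obj):
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    if isinstance(obj, np.integer):
        return int(obj)
    if isinstance(obj, np.floating):
        return float(obj)
    return str(obj)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _stage_seeds(config: dict) -> dict:
    seed = int(config["seed"])
    return {name: seed + i for i, name in enumerate(
        ["simulate", "effects", "categories", "clinal"])}


def run_simulation(config: dict, outdir: str) -> dict:
    """Generate and write the synthetic inputs; returns the in-memory objects."""
    validate_config(config)
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    stage_seeds = _stage_seeds(config)
    g = config["genome"]
    spec = synthetic_data.GenomeSpec(
        n_chromosomes=g["n_chromosomes"], chrom_length=g["chrom_length"],
        n_genes=g["n_genes"], exons_per_gene=g["exons_per_gene"],
        gene_length_range=tuple(g["gene_length_range"]),
        min_intergenic_gap=g.get("min_intergenic_gap", 300),
    )
    genome, annotation = synthetic_data.generate_annotation(spec, stage_seeds["simulate"])
    probes = synthetic_data.generate_probes(
        genome, probe_length=config["probes"]["length"], step=config["probes"]["step"])
    design = synthetic_data.make_design(
        replicates=config["design"]["replicates"],
        stages=tuple(config["design"]["stages"]))
    effects = synthetic_data.EffectSpec(seed=stage_seeds["effects"], **config["effects"])
    intensities, truth = synthetic_data.simulate_intensities(
        probes, design, effects, annotation)
    clinal_table = synthetic_data.generate_clinal_table(
        seed=stage_seeds["clinal"], **config["clinal"])

    ctio.write_fasta(genome, out / "genome.fa")
    annotation.to_gff3(out / "annotation.gff3")
    ctio.write_tsv(probes, out / "probes.tsv")
    ctio.write_tsv(design, out / "design.tsv")
    intensities.rename_axis("probe_id").reset_index().pipe(
        ctio.write_tsv, out / "intensities.tsv")
    ctio.write_tsv(truth, out / "truth.tsv")
    ctio.write_tsv(clinal_table, out / "clinal_table.tsv")
    return {"genome": genome, "annotation": annotation, "probes": probes,
            "design": design, "intensities": intensities, "truth": truth,
            "clinal_table": clinal_table}


def run_pipeline(config: dict, outdir: str) -> dict:
    """Run the full synthetic pipeline; returns (and writes) the manifest.

    A failing stage halts the run with the stage named in the error.
    """
    validate_config(config)
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    stage_seeds = _stage_seeds(config)

    current = "simulate"
    try:
        sim = run_simulation(config, outdir)
        genome, annotation, probes = sim["genome"], sim["annotation"], sim["probes"]
        design, intensities = sim["design"], sim["intensities"]
        clinal_table = sim["clinal_table"]

        current = "annotate"
        locations = probe_annotation.map_probes(probes, genome)
        mapping = probe_annotation.filter_unique(locations)
        retained = mapping[mapping["status"] == "unique"].copy()
        retained["start"] = retained["start"].astype(int)
        labels = probe_annotation.label_probes(
            retained, annotation, probe_length=config["probes"]["length"])
        regions = probe_annotation.define_intergenic_regions(annotation)
        ctio.write_tsv(labels, out / "labelled_probes.tsv")
        bed = regions.assign(bed_start=regions["start"] - 1)[
            ["chrom", "bed_start", "end", "region_id"]]
        bed.to_csv(out / "intergenic_regions.bed", sep="\t", header=False,
                   index=False)

        current = "preprocess"
        pp = config["preprocessing"]
        kept = intensities.loc[labels["probe_id"]]
        normalized = preprocessing.preprocess(
            kept, retained, half_window=pp["half_window"],
            percentile=pp["percentile"], span=pp["loess_span"])
        normalized.rename_axis("probe_id").reset_index().pipe(
            ctio.write_tsv, out / "normalized.tsv")

        thresholds = region_calling.ScenarioThresholds(**config["thresholds"])
        stage_calls = {}
        stats_by_stage = {}
        for stage in config["design"]["stages"]:
            current = f"teststats[{stage}]"
            stats = probewise_stats.probe_statistics(normalized, design, stage)
            stats_by_stage[stage] = stats
            stats.rename_axis("probe_id").reset_index().pipe(
                ctio.write_tsv, out / f"stats_{stage}.tsv")
            current = f"call[{stage}]"
            flags = region_calling.call_probes_frame(stats, retained, thresholds)
            calls = region_calling.summarize_calls(flags, stats, labels, regions)
            stage_calls[stage] = calls
            flags.rename_axis("probe_id").reset_index().pipe(
                ctio.write_tsv, out / f"calls_{stage}.tsv")
            ctio.write_tsv(calls.genes, out / f"genes_{stage}.tsv")
            ctio.write_tsv(calls.intergenic, out / f"intergenic_{stage}.tsv")

        current = "overlap"
        stages = list(config["design"]["stages"])
        overlap_report = {}
        if len(stages) >= 2:
            universe = sorted(set(labels["gene_id"].dropna()))
            a = list(stage_calls[stages[0]].genes["gene_id"])
            b = list(stage_calls[stages[1]].genes["gene_id"])
            k, p = region_calling.overlap_test(a, b, len(universe))
            overlap_report = {
                "stage_a": stages[0], "stage_b": stages[1],
                "n_a": len(a), "n_b": len(b), "universe": len(universe),
                "overlap": k, "p": p,
            }
            (out / "overlap.json").write_text(
                json.dumps(overlap_report, indent=2, sort_keys=True,
                           default=_json_default) + "\n")

        current = "enrich"
        enr = config["enrichment"]
        gene_universe = sorted(set(labels["gene_id"].dropna()))
        categories = generate_categories(
            gene_universe, enr["n_categories"], enr["size_range"],
            stage_seeds["categories"])
        ctio.write_gmt(categories, out / "categories.gmt")
        for stage in stages:
            for direction in ("up_in_north", "up_in_south"):
                ranked = enrichment.rank_genes(stats_by_stage[stage], labels,
                                               direction=direction)
                scored = enrichment.score_categories(ranked, categories,
                                                     method=enr["method"])
                scored = enrichment.permutation_fdr(
                    scored, ranked, categories,
                    n_permutations=enr["n_permutations"],
                    seed=stage_seeds["categories"], method=enr["method"])
                ctio.write_tsv(scored, out / f"enrichment_{stage}_{direction}.tsv")

        current = "cline"
        cline = clinal_stats.cline_report(clinal_table)
        (out / "cline.json").write_text(
            json.dumps(cline, indent=2, sort_keys=True,
                       default=_json_default) + "\n")
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {current!r} failed: {exc}") from exc

    manifest = {
        "config": config,
        "stage_seeds": stage_seeds,
        "overlap": overlap_report,
        "outputs": {
            p.name: _sha256(p)
            for p in sorted(out.iterdir())
            if p.is_file() and p.name != "manifest.json"
        },
    }
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True, default=_json_default) + "\n")
    return manifest
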