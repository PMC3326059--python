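"""Synthetic genomes, tiling probes, array intensities and clinal tables.

This module plays the role of the wet lab: it produces a small random genome
with non-overlapping genes, a fixed-step tiling-probe layout over it, a
North/South x larval-stage array design, and raw probe intensities that
superimpose, on the log2 scale,

* a per-gene expression level (exonic probes) or a low genomic baseline,
* a per-probe affinity offset (tiling probes differ in hybridization
  efficiency; modelled as Normal(0, probe_affinity_sd)),
* Normal replicate noise whose per-probe true variance is itself random —
  scaled inverse chi-square with ``noise_prior_df`` degrees of freedom about
  ``replicate_noise_sd**2`` — the probe-to-probe variance heterogeneity
  (cross-hybridization, sequence effects, polymorphism between populations)
  that makes empirical-Bayes variance moderation meaningful on real arrays,
* and, for a planted minority of genes, a North-vs-South log2 fold change
  applied uniformly to the gene's exonic probes at both stages.

On top of the exponentiated (base-2) signal, each array carries a smooth
spatial background that is additive on the raw intensity scale — one
sinusoid cycle per chromosome with a random phase plus a per-array offset,
both scaled by ``background_trend_amplitude`` (raw intensity units), the way
optical background varies slowly across a scanned array. This is the
structure the windowed-percentile background subtraction is meant to remove.
Everything is deterministic given the seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Mapping, Optional, Tuple

import numpy as np
import pandas as pd

from .annotation import EXON_COLUMNS, GENE_COLUMNS, GenomeAnnotation
from .probe_annotation import label_probes

_BASES = np.array(list("ACGT"))

# default latitude span: signed degrees, tropical north to temperate south
# of the eastern Australian cline
_LAT_NORTH, _LAT_SOUTH = -16.0, -43.0


@dataclass(frozen=True)
class GenomeSpec:
    """Layout parameters for the synthetic genome."""

    n_chromosomes: int = 2
    chrom_length: int = 200_000
    n_genes: int = 80
    exons_per_gene: int = 3
    gene_length_range: Tuple[int, int] = (1500, 3000)
    min_intergenic_gap: int = 300

    def __post_init__(self) -> None:
        if self.n_chromosomes < 1 or self.chrom_length < 1:
            raise ValueError("need at least one chromosome of positive length")
        if self.n_genes < 0 or self.exons_per_gene < 1:
            raise ValueError("invalid gene/exon counts")
        lo, hi = self.gene_length_range
        if not (1 <= lo <= hi <= self.chrom_length):
            raise ValueError("invalid gene_length_range")


@dataclass(frozen=True)
class EffectSpec:
    """Planted-signal and noise parameters for the intensity simulator.

    ``log2_fold_change`` is the North-minus-South shift applied to planted
    genes (sign drawn per gene); the standard deviations are on the log2
    scale while ``background_trend_amplitude`` is on the raw intensity scale
    (the additive optical background of an array; the default is of the same
    order as the raw baseline 2**6 of non-transcribed positions).
    """

    de_gene_fraction: float = 0.10
    log2_fold_change: float = 2.0
    probe_affinity_sd: float = 0.7
    background_trend_amplitude: float = 50.0
    replicate_noise_sd: float = 0.5
    noise_prior_df: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.de_gene_fraction <= 1.0:
            raise ValueError("de_gene_fraction must be in [0, 1]")
        for name in ("probe_affinity_sd", "background_trend_amplitude", "replicate_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not self.noise_prior_df > 0:
            raise ValueError("noise_prior_df must be positive (may be inf)")


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=length)])


def _partition_with_minimum(rng: np.random.Generator, total: int, parts: int,
                            minimum: int) -> np.ndarray:
    """Random composition of ``total`` into ``parts`` parts each >= minimum."""
    slack = total - parts * minimum
    if slack < 0:
        raise ValueError("infeasible partition")
    if parts == 1:
        return np.array([total])
    cuts = np.sort(rng.integers(0, slack + 1, size=parts - 1))
    extras = np.diff(np.concatenate([[0], cuts, [slack]]))
    return extras + minimum


def generate_annotation(spec: GenomeSpec, seed: int) -> Tuple[Dict[str, str], GenomeAnnotation]:
    """Generate a random genome and a non-overlapping gene/exon annotation.

    Genes are distributed as evenly as possible across chromosomes and placed
    with at least ``spec.min_intergenic_gap`` bp between neighbours and the
    chromosome ends. Each gene is split into ``exons_per_gene`` exons with
    introns in between; the first and last exon abut the gene boundaries.
    Raises ``ValueError`` when the requested genes cannot be packed.
    """
    rng = np.random.default_rng(seed)
    chroms = [f"chr{i + 1}" for i in range(spec.n_chromosomes)]
    genome = {c: _random_sequence(rng, spec.chrom_length) for c in chroms}
    chrom_lengths = {c: spec.chrom_length for c in chroms}

    per_chrom = np.full(spec.n_chromosomes, spec.n_genes // spec.n_chromosomes)
    per_chrom[: spec.n_genes % spec.n_chromosomes] += 1

    gene_rows, exon_rows = [], []
    gene_counter = 0
    lo, hi = spec.gene_length_range
    for chrom, n in zip(chroms, per_chrom):
        if n == 0:
            continue
        lengths = rng.integers(lo, hi + 1, size=n)
        occupied = int(lengths.sum()) + (n + 1) * spec.min_intergenic_gap
        if occupied > spec.chrom_length:
            raise ValueError(
                f"cannot pack {n} genes (total {lengths.sum()} bp + gaps) "
                f"into {spec.chrom_length} bp chromosome {chrom}"
            )
        gaps = _partition_with_minimum(
            rng, spec.chrom_length - int(lengths.sum()), n + 1, spec.min_intergenic_gap
        )
        pos = 0
        for g_len, gap in zip(lengths, gaps[:-1]):
            start = pos + int(gap) + 1  # 1-based
            end = start + int(g_len) - 1
            gene_counter += 1
            gene_id = f"gene{gene_counter:04d}"
            strand = "+" if rng.random() < 0.5 else "-"
            gene_rows.append(
                {"gene_id": gene_id, "chrom": chrom, "start": start, "end": end,
                 "strand": strand}
            )
            exon_rows.extend(_split_exons(rng, gene_id, chrom, start, end,
                                          spec.exons_per_gene))
            pos = end
    genes = pd.DataFrame(gene_rows, columns=GENE_COLUMNS)
    exons = pd.DataFrame(exon_rows, columns=EXON_COLUMNS)
    return genome, GenomeAnnotation(chrom_lengths=chrom_lengths, genes=genes, exons=exons)


def _split_exons(rng: np.random.Generator, gene_id: str, chrom: str, start: int,
                 end: int, n_exons: int, min_piece: int = 60) -> list:
    length = end - start + 1
    n_parts = 2 * n_exons - 1  # exon/intron alternation, exons at both ends
    while n_parts > 1 and n_parts * min_piece > length:
        n_exons -= 1
        n_parts = 2 * n_exons - 1
    pieces = _partition_with_minimum(rng, length, n_parts, min_piece if n_parts > 1 else 1)
    rows = []
    pos = start
    for i, piece in enumerate(pieces):
        if i % 2 == 0:  # exon
            rows.append({"gene_id": gene_id, "chrom": chrom,
                         "start": pos, "end": pos + int(piece) - 1})
        pos += int(piece)
    return rows


def generate_probes(genome: Mapping[str, str], probe_length: int = 25,
                    step: int = 40) -> pd.DataFrame:
    """Tile each chromosome with fixed-step probes extracted from the genome.

    Returns a DataFrame ``probe_id, chrom, start, strand, sequence`` ordered by
    (chromosome, start); starts are 1-based and probes are plus-strand copies
    of the genomic sequence.
    """
    if step < 1:
        raise ValueError("step must be >= 1")
    rows = []
    for chrom in genome:
        seq = genome[chrom]
        if probe_length > len(seq):
            raise ValueError(f"probe_length {probe_length} exceeds {chrom} length")
        for start0 in range(0, len(seq) - probe_length + 1, step):
            rows.append(
                {"probe_id": f"{chrom}:{start0 + 1}",
                 "chrom": chrom, "start": start0 + 1, "strand": "+",
                 "sequence": seq[start0:start0 + probe_length]}
            )
    return pd.DataFrame(rows, columns=["probe_id", "chrom", "start", "strand", "sequence"])


def make_design(replicates: int = 5, stages: Tuple[str, ...] = ("L2", "L3")) -> pd.DataFrame:
    """North/South x stage x replicate array design table."""
    if replicates < 2:
        raise ValueError("need >= 2 replicates per group for variance estimation")
    rows = [
        {"array_id": f"{end}_{stage}_r{rep}", "cline_end": end, "stage": stage,
         "replicate": rep}
        for stage in stages
        for end in ("North", "South")
        for rep in range(1, replicates + 1)
    ]
    return pd.DataFrame(rows)


def simulate_intensities(
    probes: pd.DataFrame,
    design: pd.DataFrame,
    effects: EffectSpec,
    annotation: GenomeAnnotation,
    baseline_log2: float = 6.0,
    gene_level_mean: float = 9.0,
    gene_level_sd: float = 1.0,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate raw tiling-array intensities with planted clinal DE genes.

    Returns ``(intensities, truth)`` where ``intensities`` is a probes x arrays
    DataFrame on the raw scale (2**log2) and ``truth`` lists the planted genes
    with their North-minus-South log2 fold change and direction
    (``up_in_north`` / ``up_in_south``). DE genes are drawn only from genes
    with at least one exonic probe.
    """
    if len(design) == 0:
        raise ValueError("design table is empty")
    rng = np.random.default_rng(effects.seed)
    labels = label_probes(probes, annotation)
    n_probes = len(probes)
    probe_gene = labels["gene_id"].to_numpy(dtype=object)
    exonic = (labels["label"] == "exonic").to_numpy()

    gene_ids = list(annotation.genes["gene_id"])
    gene_mu = {g: rng.normal(gene_level_mean, gene_level_sd) for g in gene_ids}
    affinity = rng.normal(0.0, effects.probe_affinity_sd, size=n_probes)

    genes_with_exonic = sorted(set(probe_gene[exonic]) - {None})
    n_de = int(round(effects.de_gene_fraction * len(gene_ids)))
    n_de = min(n_de, len(genes_with_exonic))
    de_genes = sorted(rng.choice(genes_with_exonic, size=n_de, replace=False)) if n_de else []
    de_sign = {g: (1 if rng.random() < 0.5 else -1) for g in de_genes}

    base = np.full(n_probes, baseline_log2)
    for i in range(n_probes):
        if exonic[i]:
            base[i] = gene_mu[probe_gene[i]]

    fc = np.zeros(n_probes)  # North-minus-South shift per probe
    for i in range(n_probes):
        g = probe_gene[i]
        if exonic[i] and g in de_sign:
            fc[i] = de_sign[g] * effects.log2_fold_change

    pos = probes["start"].to_numpy(dtype=float)
    chrom_len = np.array([annotation.chrom_lengths[c] for c in probes["chrom"]], dtype=float)

    # per-probe true noise sd: scaled inverse-chi-square heterogeneity
    if math.isinf(effects.noise_prior_df):
        probe_sd = np.full(n_probes, effects.replicate_noise_sd)
    else:
        d0 = effects.noise_prior_df
        probe_sd = effects.replicate_noise_sd * np.sqrt(
            d0 / rng.chisquare(d0, size=n_probes))

    cols = {}
    for _, arr in design.iterrows():
        phase = rng.uniform(0, 2 * np.pi)
        offset = effects.background_trend_amplitude * rng.uniform(0.0, 0.5)
        bg = effects.background_trend_amplitude * 0.5 * (
            1.0 + np.sin(2 * np.pi * pos / chrom_len + phase)
        ) + offset
        noise = probe_sd * rng.standard_normal(n_probes)
        shift = fc / 2.0 if arr["cline_end"] == "North" else -fc / 2.0
        cols[arr["array_id"]] = np.power(2.0, base + affinity + noise + shift) + bg
    intensities = pd.DataFrame(cols, index=probes["probe_id"].to_numpy())
    truth = pd.DataFrame(
        {
            "gene_id": de_genes,
            "log2_fold_change": [de_sign[g] * effects.log2_fold_change for g in de_genes],
            "direction": ["up_in_north" if de_sign[g] > 0 else "up_in_south"
                          for g in de_genes],
        }
    )
    return intensities, truth


def generate_clinal_table(
    n_populations: int = 15,
    slope: float = 0.05,
    intercept: float = 3.0,
    noise_sd: float = 0.1,
    outlier_index: Optional[int] = None,
    outlier_shift: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Latitude/value table for cline regression: value = a + b*latitude + noise.

    Latitudes are evenly spaced signed degrees spanning a southern-hemisphere
    transect (south negative). An optional single outlier is displaced by
    ``outlier_shift``.
    """
    if n_populations < 3:
        raise ValueError("need >= 3 populations for a cline regression")
    if outlier_index is not None and not (0 <= outlier_index < n_populations):
        raise ValueError("outlier_index out of range")
    rng = np.random.default_rng(seed)
    lat = np.linspace(_LAT_SOUTH, _LAT_NORTH, n_populations)
    values = intercept + slope * lat + rng.normal(0.0, noise_sd, size=n_populations)
    if outlier_index is not None:
        values[outlier_index] += outlier_shift
    return pd.DataFrame(
        {"population_id": [f"pop{i + 1:02d}" for i in range(n_populations)],
         "latitude": lat, "value": values}
    )
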