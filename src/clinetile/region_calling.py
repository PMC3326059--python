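"""Three-scenario DE probe calling, gene/region summaries and overlap testing.

A probe is called differentially expressed when any of three scenarios fires
on the position-ordered p-values of its chromosome:

* short  — its own p-value is below 1e-5;
* medium — the geometric mean of its p-value and the immediately flanking
  probe on each side is below 0.01;
* long   — the Gaussian-weighted geometric mean (variance 5 in probe-index
  units, 10 probes on each side) of the 21-probe window is below 0.1.

Windows are truncated at chromosome ends with the weights renormalized.
Called probes are summarized to distinct genes (via exonic/intronic labels,
direction from the sign of the mean effect) and to distinct intergenic
regions; gene-list overlap between stages is assessed with the hypergeometric
upper tail.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

from .probe_annotation import assign_intergenic_region


@dataclass(frozen=True)
class ScenarioThresholds:
    short_p: float = 1e-5
    medium_p: float = 0.01
    medium_flank: int = 1  # probes on each side; 1 -> 3-probe window
    long_p: float = 0.1
    long_halfwidth: int = 10
    gaussian_variance: float = 5.0

    def __post_init__(self) -> None:
        for name in ("short_p", "medium_p", "long_p"):
            if not 0 < getattr(self, name) < 1:
                raise ValueError(f"{name} must be in (0, 1)")
        if self.medium_flank < 0 or self.long_halfwidth < 0:
            raise ValueError("window widths must be >= 0")
        if self.gaussian_variance <= 0:
            raise ValueError("gaussian_variance must be positive")


@dataclass
class RegionCallSet:
    """Per-probe scenario flags plus derived gene and intergenic-region lists."""

    probe_flags: pd.DataFrame
    genes: pd.DataFrame
    intergenic: pd.DataFrame
    counts: Tuple[int, int, int] = field(default=(0, 0, 0))


def weighted_geometric_mean(p: np.ndarray, weights: np.ndarray) -> float:
    """exp(sum w*log p / sum w); lies between min(p) and max(p)."""
    p = np.asarray(p, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must be in (0, 1]")
    if np.any(weights < 0) or weights.sum() == 0:
        raise ValueError("weights must be >= 0 and not all zero")
    return float(np.exp(np.sum(weights * np.log(p)) / weights.sum()))


def _windowed_log_gm(logp: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Weighted mean of log p over a centered kernel, truncated at the ends
    with weights renormalized."""
    # centered slice of the full convolution: robust when the chromosome is
    # shorter than the kernel (np.convolve 'same' keys on the longer input)
    half = len(kernel) // 2
    num = np.convolve(logp, kernel[::-1], mode="full")[half: half + len(logp)]
    den = np.convolve(np.ones_like(logp), kernel[::-1],
                      mode="full")[half: half + len(logp)]
    return num / den


def gaussian_kernel(halfwidth: int, variance: float) -> np.ndarray:
    i = np.arange(-halfwidth, halfwidth + 1, dtype=float)
    return np.exp(-(i ** 2) / (2.0 * variance))


def call_probes(p: np.ndarray,
                thresholds: ScenarioThresholds = ScenarioThresholds()) -> pd.DataFrame:
    """Scenario flags for one chromosome's position-ordered p-values.

    Returns a DataFrame with boolean columns ``short, medium, long, any``.
    """
    p = np.asarray(p, dtype=float)
    if np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must be in (0, 1]; resolve degenerate probes first")
    logp = np.log(p)
    short = p < thresholds.short_p
    med_kernel = np.ones(2 * thresholds.medium_flank + 1)
    medium = np.exp(_windowed_log_gm(logp, med_kernel)) < thresholds.medium_p
    long_kernel = gaussian_kernel(thresholds.long_halfwidth, thresholds.gaussian_variance)
    long_flag = np.exp(_windowed_log_gm(logp, long_kernel)) < thresholds.long_p
    return pd.DataFrame(
        {"short": short, "medium": medium, "long": long_flag,
         "any": short | medium | long_flag}
    )


def call_probes_frame(stats: pd.DataFrame, probes: pd.DataFrame,
                      thresholds: ScenarioThresholds = ScenarioThresholds()
                      ) -> pd.DataFrame:
    """Apply :func:`call_probes` per chromosome of a probe-stats table.

    ``stats`` is indexed by probe_id with a ``p`` column; ``probes`` supplies
    ``probe_id, chrom, start`` and must be position-sorted within chromosome.
    Returns flags indexed by probe_id in the input order of ``stats``.
    """
    meta = probes.set_index("probe_id").loc[stats.index]
    frames = []
    for chrom in meta["chrom"].unique():
        mask = meta["chrom"] == chrom
        starts = meta.loc[mask, "start"].to_numpy()
        if np.any(np.diff(starts) < 0):
            raise ValueError(f"probes on {chrom} are not position-sorted")
        flags = call_probes(stats.loc[mask.to_numpy(), "p"].to_numpy(), thresholds)
        flags.index = stats.index[mask.to_numpy()]
        frames.append(flags)
    return pd.concat(frames).loc[stats.index]


def summarize_calls(flags: pd.DataFrame, stats: pd.DataFrame,
                    labels: pd.DataFrame, intergenic_regions: pd.DataFrame
                    ) -> RegionCallSet:
    """Summarize called probes into gene and intergenic-region lists.

    ``labels`` is the probe label table (``probe_id, chrom, start, label,
    gene_id``); every called probe must appear in it. Gene direction is the
    sign of the mean effect of the gene's called probes (effect is
    North minus South, so positive means up in the North).
    """
    called_ids = flags.index[flags["any"].to_numpy()]
    lab = labels.set_index("probe_id")
    missing = [pid for pid in called_ids if pid not in lab.index]
    if missing:
        raise ValueError(f"called probes without labels: {missing[:5]}")
    sub = lab.loc[called_ids].copy()
    sub["effect"] = stats.loc[called_ids, "effect"].to_numpy()
    sub["p"] = stats.loc[called_ids, "p"].to_numpy()

    gene_rows = []
    genic = sub[sub["gene_id"].notna()]
    for gene_id, grp in genic.groupby("gene_id"):
        mean_effect = float(grp["effect"].mean())
        gene_rows.append(
            {"gene_id": gene_id,
             "direction": "up_in_north" if mean_effect > 0 else "up_in_south",
             "n_probes": len(grp), "mean_effect": mean_effect,
             "best_p": float(grp["p"].min())}
        )
    genes = pd.DataFrame(
        gene_rows,
        columns=["gene_id", "direction", "n_probes", "mean_effect", "best_p"],
    ).sort_values("gene_id").reset_index(drop=True) if gene_rows else pd.DataFrame(
        columns=["gene_id", "direction", "n_probes", "mean_effect", "best_p"])

    inter = sub[sub["label"] == "intergenic"].reset_index()
    if len(inter) and len(intergenic_regions):
        inter["region_id"] = assign_intergenic_region(inter, intergenic_regions).to_numpy()
        region_rows = [
            {"region_id": rid, "n_probes": len(grp), "best_p": float(grp["p"].min())}
            for rid, grp in inter.groupby("region_id")
        ]
    else:
        region_rows = []
    regions = pd.DataFrame(
        region_rows, columns=["region_id", "n_probes", "best_p"]
    ).sort_values("region_id").reset_index(drop=True) if region_rows else pd.DataFrame(
        columns=["region_id", "n_probes", "best_p"])

    counts = (int(len(called_ids)), int(len(genes)), int(len(regions)))
    return RegionCallSet(probe_flags=flags, genes=genes, intergenic=regions,
                         counts=counts)


def overlap_test(list_a: Iterable[str], list_b: Iterable[str],
                 universe_size: int) -> Tuple[int, float]:
    """Hypergeometric upper-tail test of gene-list overlap.

    Returns ``(k, p)`` where k is the intersection size and p the probability
    of an intersection at least that large when both lists are drawn uniformly
    from a universe of ``universe_size`` genes.
    """
    a, b = set(list_a), set(list_b)
    if universe_size < max(len(a), len(b)):
        raise ValueError("universe smaller than a gene list")
    k = len(a & b)
    p = float(sps.hypergeom.sf(k - 1, universe_size, len(a), len(b)))
    return k, p
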