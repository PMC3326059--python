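"""Rank-based category enrichment with a permutation false-discovery rate.

Genes are ranked by a per-gene signed moderated t (the probe with largest
absolute t represents the gene); a category of m genes is scored by the
Wilcoxon rank sum W = sum of its members' ranks, and its one-sided p-value is
P(W' <= W) under uniform random assignment of m ranks out of N without
replacement — computed exactly by a subset-sum convolution when feasible and
by the normal approximation (mean m(N+1)/2, variance m(N-m)(N+1)/12, with
continuity correction) otherwise. The false-discovery rate is estimated by
gene-rank permutation: category memberships are held fixed while gene ranks
are shuffled, the full battery of category p-values is recomputed per
permutation, and FDR(c) is the expected number of null categories at or below
p(c) divided by the observed number.
"""

from __future__ import annotations

import math
from typing import Dict, Iterable, List, Mapping, Optional

import numpy as np
import pandas as pd
from scipy import stats as sps

from .annotation import GenomeAnnotation

_EXACT_BUDGET = 5e7  # N * m * W cells for the exact convolution


def rank_genes(probe_stats: pd.DataFrame, labels: pd.DataFrame,
               direction: str = "up_in_north",
               summary: str = "max_abs_t") -> pd.DataFrame:
    """Collapse probe t-statistics to a ranked gene list.

    ``probe_stats`` is indexed by probe_id with a ``t`` column; ``labels``
    maps probes to genes. The per-gene statistic is the probe t with largest
    absolute value (or the mean t with ``summary="mean_t"``). Rank 1 is the
    most up-regulated gene in the requested direction (``up_in_north`` sorts
    by descending t since effects are North minus South); ties break by
    gene_id.
    """
    if direction not in ("up_in_north", "up_in_south"):
        raise ValueError("direction must be 'up_in_north' or 'up_in_south'")
    lab = labels.set_index("probe_id")
    common = probe_stats.index.intersection(lab.index)
    df = pd.DataFrame({"t": probe_stats.loc[common, "t"],
                       "gene_id": lab.loc[common, "gene_id"]})
    df = df[df["gene_id"].notna()]
    if df.empty:
        raise ValueError("no probes map to genes")
    if summary == "max_abs_t":
        idx = df.groupby("gene_id")["t"].apply(lambda s: s.abs().idxmax())
        gene_t = df.loc[idx.to_numpy(), "t"]
        gene_t.index = idx.index
    elif summary == "mean_t":
        gene_t = df.groupby("gene_id")["t"].mean()
    else:
        raise ValueError(f"unknown summary {summary!r}")
    ascending = direction == "up_in_south"
    ranked = gene_t.reset_index().rename(columns={"t": "gene_t"})
    ranked = ranked.sort_values(["gene_t", "gene_id"],
                                ascending=[ascending, True]).reset_index(drop=True)
    ranked["rank"] = np.arange(1, len(ranked) + 1)
    return ranked


def _exact_tail(N: int, m: int, W: int) -> float:
    """P(sum of m distinct ranks from 1..N <= W), exact by convolution."""
    w_min = m * (m + 1) // 2
    if W < w_min:
        return 0.0
    W = min(W, m * N - m * (m - 1) // 2)
    # f[j, s] = number of j-subsets of {1..v} with sum s, accumulated over v
    f = np.zeros((m + 1, W + 1))
    f[0, 0] = 1.0
    for v in range(1, N + 1):
        for j in range(min(m, v), 0, -1):
            if v <= W:
                f[j, v:] += f[j - 1, :-v]
    count = f[m].sum()
    return float(count / math.comb(N, m))


def _normal_tail(N: int, m: int, W: float) -> float:
    mean = m * (N + 1) / 2.0
    var = m * (N - m) * (N + 1) / 12.0
    if var == 0:
        return 1.0 if W >= mean else 0.0
    return float(sps.norm.cdf((W + 0.5 - mean) / math.sqrt(var)))


def category_score(ranked: pd.DataFrame, members: Iterable[str],
                   method: str = "auto") -> tuple:
    """Rank-sum score and one-sided p-value for one category.

    ``method`` is ``"exact"``, ``"normal"`` or ``"auto"`` (exact when the
    convolution fits a fixed work budget). Returns ``(m, W, p)``.
    Raises when the category is empty, not a subset of the ranked genes, or
    covers the whole list.
    """
    members = set(members)
    rank_of = dict(zip(ranked["gene_id"], ranked["rank"]))
    N = len(ranked)
    missing = members - rank_of.keys()
    if missing:
        raise ValueError(f"category members absent from gene list: {sorted(missing)[:5]}")
    m = len(members)
    if m == 0:
        raise ValueError("empty category")
    if m == N:
        raise ValueError("category covers the entire gene list")
    W = int(sum(rank_of[g] for g in members))
    p = _score_tail(N, m, W, method)
    return m, W, p


def _score_tail(N: int, m: int, W: int, method: str = "auto") -> float:
    if method == "auto":
        method = "exact" if N * m * (W + 1) <= _EXACT_BUDGET else "normal"
    if method == "exact":
        return _exact_tail(N, m, W)
    if method == "normal":
        return _normal_tail(N, m, W)
    raise ValueError(f"unknown method {method!r}")


def score_categories(ranked: pd.DataFrame, categories: Mapping[str, list],
                     method: str = "normal") -> pd.DataFrame:
    """Score every category; returns ``category_id, m, W, p`` sorted by p."""
    rows = []
    for name, members in categories.items():
        m, W, p = category_score(ranked, members, method=method)
        rows.append({"category_id": name, "m": m, "W": W, "p": p})
    return pd.DataFrame(rows).sort_values(["p", "category_id"]).reset_index(drop=True)


def permutation_fdr(results: pd.DataFrame, ranked: pd.DataFrame,
                    categories: Mapping[str, list], n_permutations: int = 1000,
                    seed: int = 0, method: str = "normal") -> pd.DataFrame:
    """Gene-rank-permutation FDR for a scored category battery.

    For each permutation the gene-to-rank assignment is shuffled (category
    memberships fixed) and all category p-values recomputed with the same
    scoring method; FDR(c) = mean null count at or below p(c) divided by the
    observed count, capped at 1. Adds an ``fdr`` column to ``results``.
    """
    if n_permutations < 100:
        raise ValueError("need >= 100 permutations")
    rng = np.random.default_rng(seed)
    N = len(ranked)
    gene_pos = {g: i for i, g in enumerate(ranked["gene_id"])}
    member_idx = {
        c: np.array([gene_pos[g] for g in categories[c]], dtype=int)
        for c in results["category_id"]
    }
    null_p: List[np.ndarray] = []
    names = list(results["category_id"])
    sizes = {c: len(member_idx[c]) for c in names}
    for _ in range(n_permutations):
        perm = rng.permutation(N) + 1
        null_p.append(np.array([
            _score_tail(N, sizes[c], int(perm[member_idx[c]].sum()), method)
            for c in names
        ]))
    null_mat = np.sort(np.concatenate(null_p))
    obs = np.sort(results["p"].to_numpy())
    out = results.copy()
    fdrs = []
    for p in results["p"]:
        expected = np.searchsorted(null_mat, p, side="right") / n_permutations
        observed = np.searchsorted(obs, p, side="right")
        fdrs.append(min(1.0, expected / observed) if observed else 1.0)
    out["fdr"] = fdrs
    return out


def positional_category(annotation: GenomeAnnotation, chrom: str, start: int,
                        end: int) -> List[str]:
    """Genes whose body overlaps [start, end] on ``chrom`` by >= 1 bp.

    Usable as a category like any functional annotation (chromosomal-window
    categories).
    """
    if chrom not in annotation.chrom_lengths:
        raise ValueError(f"unknown chromosome {chrom}")
    genes = annotation.genes
    hit = genes[(genes["chrom"] == chrom) & (genes["start"] <= end)
                & (genes["end"] >= start)]
    return sorted(hit["gene_id"])
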