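"""Probe-to-genome mapping, unique-location filtering and genomic labelling.

Probes are matched against both strands of the genome allowing at most one
substitution (Hamming distance <= 1; indels are out of scope since they would
change the probe-length semantics of a tiling array). Only probes mapping to
a single genomic location are retained for statistics. Each retained probe is
labelled ``exonic`` if its interval overlaps any exon by >= 1 bp, else
``intronic`` if it overlaps any gene body, else ``intergenic`` — the
precedence is exon > gene body > intergenic, so a probe straddling a gene
boundary without touching an exon is intronic.

The production mapper uses a pigeonhole seed index (any match with <= k
mismatches contains an exact match of one of k+1 probe chunks); tests check
it against a per-base brute-force scan.
"""

from __future__ import annotations

from bisect import bisect_left, bisect_right
from collections import defaultdict
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Tuple

import numpy as np
import pandas as pd

from .annotation import GenomeAnnotation

_COMPLEMENT = str.maketrans("ACGT", "TGCA")
_VALID = frozenset("ACGT")

LABELS = ("exonic", "intronic", "intergenic")


@dataclass(frozen=True)
class Location:
    """A probe match: 1-based start of the matched genomic interval."""

    chrom: str
    start: int
    strand: str
    mismatches: int


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _check_sequence(seq: str) -> str:
    seq = seq.upper()
    bad = set(seq) - _VALID
    if bad:
        raise ValueError(f"probe contains non-ACGT bases: {sorted(bad)}")
    return seq


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def _chunk_offsets(length: int, n_chunks: int) -> List[Tuple[int, int]]:
    """Split [0, length) into n_chunks near-equal (offset, size) chunks."""
    base, extra = divmod(length, n_chunks)
    offsets = []
    pos = 0
    for i in range(n_chunks):
        size = base + (1 if i < extra else 0)
        offsets.append((pos, size))
        pos += size
    return offsets


def _candidate_starts(pattern: str, text: str, max_mismatches: int) -> Iterable[int]:
    """Pigeonhole candidates: starts where an exact chunk of the pattern occurs."""
    candidates = set()
    n = len(text)
    for offset, size in _chunk_offsets(len(pattern), max_mismatches + 1):
        chunk = pattern[offset:offset + size]
        pos = text.find(chunk)
        while pos != -1:
            start = pos - offset
            if 0 <= start <= n - len(pattern):
                candidates.add(start)
            pos = text.find(chunk, pos + 1)
    return sorted(candidates)


def map_probe(sequence: str, genome: Mapping[str, str],
              max_mismatches: int = 1) -> List[Location]:
    """Find every genomic location matching the probe with <= max_mismatches
    substitutions on either strand.

    Minus-strand hits are positions where the genome matches the probe's
    reverse complement; ``start`` is always the leftmost genomic coordinate
    (1-based) of the matched interval.
    """
    seq = _check_sequence(sequence)
    hits: List[Location] = []
    patterns = [("+", seq), ("-", reverse_complement(seq))]
    for chrom in genome:
        text = genome[chrom].upper()
        for strand, pattern in patterns:
            for start in _candidate_starts(pattern, text, max_mismatches):
                mm = _hamming(pattern, text[start:start + len(pattern)])
                if mm <= max_mismatches:
                    hits.append(Location(chrom, start + 1, strand, mm))
    hits.sort(key=lambda h: (h.chrom, h.start, h.strand))
    return hits


class _SeedIndex:
    """Exact k-mer index over the forward genome for bulk pigeonhole lookup."""

    def __init__(self, genome: Mapping[str, str], seed_len: int):
        self.seed_len = seed_len
        self.genome = {c: genome[c].upper() for c in genome}
        self.index: Dict[str, list] = defaultdict(list)
        for chrom, text in self.genome.items():
            for i in range(len(text) - seed_len + 1):
                self.index[text[i:i + seed_len]].append((chrom, i))

    def candidates(self, pattern: str, n_chunks: int) -> Iterable[Tuple[str, int]]:
        out = set()
        k = self.seed_len
        for offset, _ in _chunk_offsets(len(pattern), n_chunks):
            # seed with the fixed-length k-mer at each chunk offset; chunk
            # sizes are >= k by construction of the caller
            for chrom, pos in self.index.get(pattern[offset:offset + k], ()):
                start = pos - offset
                if 0 <= start <= len(self.genome[chrom]) - len(pattern):
                    out.add((chrom, start))
        return sorted(out)


def map_probes(probes: pd.DataFrame, genome: Mapping[str, str],
               max_mismatches: int = 1) -> Dict[str, List[Location]]:
    """Map every probe in a probe table; returns ``{probe_id: [Location...]}``.

    Equivalent to calling :func:`map_probe` per probe but shares one k-mer
    seed index across probes.
    """
    if len(probes) == 0:
        return {}
    min_len = int(probes["sequence"].str.len().min())
    seed_len = max(1, min_len // (max_mismatches + 1))
    index = _SeedIndex(genome, seed_len)
    result: Dict[str, List[Location]] = {}
    for probe_id, seq in zip(probes["probe_id"], probes["sequence"]):
        seq = _check_sequence(seq)
        hits = []
        for strand, pattern in (("+", seq), ("-", reverse_complement(seq))):
            for chrom, start in index.candidates(pattern, max_mismatches + 1):
                mm = _hamming(pattern, index.genome[chrom][start:start + len(pattern)])
                if mm <= max_mismatches:
                    hits.append(Location(chrom, start + 1, strand, mm))
        hits.sort(key=lambda h: (h.chrom, h.start, h.strand))
        result[probe_id] = hits
    return result


def filter_unique(locations: Mapping[str, List[Location]]) -> pd.DataFrame:
    """Apply the single-location retention rule.

    Returns a DataFrame ``probe_id, status, chrom, start, strand, mismatches``
    where status is ``unique`` (retained), ``multi`` (>= 2 locations) or
    ``unmapped`` (0 locations); location columns are filled only for retained
    probes.
    """
    rows = []
    for probe_id, locs in locations.items():
        if len(locs) == 1:
            loc = locs[0]
            rows.append({"probe_id": probe_id, "status": "unique", "chrom": loc.chrom,
                         "start": loc.start, "strand": loc.strand,
                         "mismatches": loc.mismatches})
        else:
            rows.append({"probe_id": probe_id,
                         "status": "multi" if locs else "unmapped",
                         "chrom": None, "start": np.nan, "strand": None,
                         "mismatches": np.nan})
    return pd.DataFrame(
        rows, columns=["probe_id", "status", "chrom", "start", "strand", "mismatches"]
    )


class _IntervalLookup:
    """Overlap queries against sorted non-overlapping intervals per chromosome."""

    def __init__(self, table: pd.DataFrame, payload: str):
        self.by_chrom: Dict[str, tuple] = {}
        for chrom, sub in table.groupby("chrom"):
            s = sub.sort_values("start")
            self.by_chrom[chrom] = (
                list(s["start"]), list(s["end"]), list(s[payload])
            )

    def overlapping(self, chrom: str, start: int, end: int) -> List[tuple]:
        if chrom not in self.by_chrom:
            return []
        starts, ends, payload = self.by_chrom[chrom]
        lo = bisect_left(ends, start)
        hi = bisect_right(starts, end)
        return [(starts[i], ends[i], payload[i]) for i in range(lo, hi)]


def label_probe(chrom: str, start: int, end: int,
                annotation: GenomeAnnotation) -> Tuple[str, Optional[str]]:
    """Label a single probe interval; returns ``(label, gene_id_or_None)``."""
    if chrom not in annotation.chrom_lengths:
        raise ValueError(f"unknown chromosome {chrom}")
    exons = _IntervalLookup(annotation.exons, "gene_id")
    genes = _IntervalLookup(annotation.genes, "gene_id")
    return _label_one(chrom, start, end, exons, genes)


def _label_one(chrom, start, end, exons: _IntervalLookup,
               genes: _IntervalLookup) -> Tuple[str, Optional[str]]:
    exon_hits = exons.overlapping(chrom, start, end)
    if exon_hits:
        # probe may touch two exons; attribute to the exon with most overlap
        best = max(exon_hits, key=lambda h: min(end, h[1]) - max(start, h[0]))
        return "exonic", best[2]
    gene_hits = genes.overlapping(chrom, start, end)
    if gene_hits:
        return "intronic", gene_hits[0][2]
    return "intergenic", None


def label_probes(probes: pd.DataFrame, annotation: GenomeAnnotation,
                 probe_length: Optional[int] = None) -> pd.DataFrame:
    """Label every probe in a table (columns ``probe_id, chrom, start`` plus
    either ``sequence`` or an explicit ``probe_length``).

    Returns ``probe_id, chrom, start, label, gene_id`` in input order.
    """
    for chrom in probes["chrom"].unique():
        if chrom not in annotation.chrom_lengths:
            raise ValueError(f"unknown chromosome {chrom}")
    exons = _IntervalLookup(annotation.exons, "gene_id")
    genes = _IntervalLookup(annotation.genes, "gene_id")
    labels, gene_ids = [], []
    if probe_length is None:
        lengths = probes["sequence"].str.len()
    else:
        lengths = pd.Series(probe_length, index=probes.index)
    for chrom, start, length in zip(probes["chrom"], probes["start"], lengths):
        label, gene_id = _label_one(chrom, int(start), int(start) + int(length) - 1,
                                    exons, genes)
        labels.append(label)
        gene_ids.append(gene_id)
    return pd.DataFrame(
        {"probe_id": probes["probe_id"].to_numpy(),
         "chrom": probes["chrom"].to_numpy(),
         "start": probes["start"].to_numpy(),
         "label": labels, "gene_id": gene_ids}
    )


def define_intergenic_regions(annotation: GenomeAnnotation) -> pd.DataFrame:
    """Maximal intervals outside all gene boundaries, per chromosome.

    Returns ``region_id, chrom, start, end`` (1-based inclusive), sorted;
    chromosome ends are included. Abutting or overlapping genes are merged
    before taking the complement.
    """
    rows = []
    for chrom, length in annotation.chrom_lengths.items():
        sub = annotation.genes[annotation.genes["chrom"] == chrom]
        merged: List[list] = []
        for _, g in sub.sort_values("start").iterrows():
            if merged and g["start"] <= merged[-1][1] + 1:
                merged[-1][1] = max(merged[-1][1], g["end"])
            else:
                merged.append([g["start"], g["end"]])
        pos = 1
        for lo, hi in merged:
            if lo > pos:
                rows.append({"chrom": chrom, "start": pos, "end": lo - 1})
            pos = hi + 1
        if pos <= length:
            rows.append({"chrom": chrom, "start": pos, "end": length})
    df = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    df.insert(0, "region_id", [f"{r.chrom}:{r.start}-{r.end}" for r in df.itertuples()])
    return df


def assign_intergenic_region(probes: pd.DataFrame,
                             regions: pd.DataFrame) -> pd.Series:
    """Region id containing each probe's start (NaN when inside a gene)."""
    out = []
    by_chrom = {
        chrom: (list(sub["start"]), list(sub["end"]), list(sub["region_id"]))
        for chrom, sub in regions.groupby("chrom")
    }
    for chrom, start in zip(probes["chrom"], probes["start"]):
        region = None
        if chrom in by_chrom:
            starts, ends, ids = by_chrom[chrom]
            i = bisect_right(starts, int(start)) - 1
            if i >= 0 and starts[i] <= int(start) <= ends[i]:
                region = ids[i]
        out.append(region)
    return pd.Series(out, index=probes.index, name="region_id")
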