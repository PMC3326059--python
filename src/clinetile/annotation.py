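"""Gene/exon annotation container shared by the generator and the mapping stage.

Coordinates are 1-based inclusive throughout (GFF3 convention).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict

import pandas as pd

from . import io as ctio

GENE_COLUMNS = ["gene_id", "chrom", "start", "end", "strand"]
EXON_COLUMNS = ["gene_id", "chrom", "start", "end"]


@dataclass
class GenomeAnnotation:
    """Chromosome lengths plus gene and exon interval tables.

    ``genes`` has columns ``gene_id, chrom, start, end, strand``;
    ``exons`` has ``gene_id, chrom, start, end``. Every exon must lie inside
    its gene and all intervals inside their chromosome.
    """

    chrom_lengths: Dict[str, int]
    genes: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=GENE_COLUMNS))
    exons: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=EXON_COLUMNS))

    def __post_init__(self) -> None:
        self.genes = self.genes.reset_index(drop=True)
        self.exons = self.exons.reset_index(drop=True)
        self.validate()

    def validate(self) -> None:
        for _, g in self.genes.iterrows():
            if g["chrom"] not in self.chrom_lengths:
                raise ValueError(f"gene {g['gene_id']} on unknown chromosome {g['chrom']}")
            if not (1 <= g["start"] <= g["end"] <= self.chrom_lengths[g["chrom"]]):
                raise ValueError(f"gene {g['gene_id']} outside chromosome bounds")
        gene_span = {g["gene_id"]: (g["start"], g["end"]) for _, g in self.genes.iterrows()}
        for _, e in self.exons.iterrows():
            lo, hi = gene_span[e["gene_id"]]
            if not (lo <= e["start"] <= e["end"] <= hi):
                raise ValueError(f"exon of {e['gene_id']} outside its gene")
        # genes non-overlapping within a chromosome
        for chrom, sub in self.genes.groupby("chrom"):
            s = sub.sort_values("start")
            prev_end = 0
            for _, g in s.iterrows():
                if g["start"] <= prev_end:
                    raise ValueError(f"overlapping genes on {chrom}")
                prev_end = g["end"]

    def to_gff3(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("##gff-version 3\n")
            for chrom, length in self.chrom_lengths.items():
                fh.write(f"##sequence-region {chrom} 1 {length}\n")
            for _, g in self.genes.sort_values(["chrom", "start"]).iterrows():
                fh.write(
                    "\t".join(
                        [g["chrom"], "clinetile", "gene", str(g["start"]), str(g["end"]),
                         ".", g["strand"], ".", f"ID={g['gene_id']}"]
                    )
                    + "\n"
                )
            strands = {g["gene_id"]: g["strand"] for _, g in self.genes.iterrows()}
            for i, (_, e) in enumerate(self.exons.sort_values(["chrom", "start"]).iterrows()):
                fh.write(
                    "\t".join(
                        [e["chrom"], "clinetile", "exon", str(e["start"]), str(e["end"]),
                         ".", strands[e["gene_id"]], ".",
                         f"ID={e['gene_id']}.e{i};Parent={e['gene_id']}"]
                    )
                    + "\n"
                )

    @classmethod
    def from_gff3(cls, path) -> "GenomeAnnotation":
        chrom_lengths: Dict[str, int] = {}
        with open(path) as fh:
            for line in fh:
                if line.startswith("##sequence-region"):
                    _, chrom, _, end = line.split()
                    chrom_lengths[chrom] = int(end)
        df = ctio.read_gff3(path)
        genes_rows, exons_rows = [], []
        for _, row in df.iterrows():
            attrs = ctio.parse_gff_attributes(row["attributes"])
            if row["type"] == "gene":
                genes_rows.append(
                    {"gene_id": attrs["ID"], "chrom": row["seqid"],
                     "start": row["start"], "end": row["end"], "strand": row["strand"]}
                )
            elif row["type"] == "exon":
                exons_rows.append(
                    {"gene_id": attrs["Parent"], "chrom": row["seqid"],
                     "start": row["start"], "end": row["end"]}
                )
        for chrom in {r["chrom"] for r in genes_rows}:
            chrom_lengths.setdefault(
                chrom, max(r["end"] for r in genes_rows if r["chrom"] == chrom)
            )
        genes = pd.DataFrame(genes_rows, columns=GENE_COLUMNS)
        exons = pd.DataFrame(exons_rows, columns=EXON_COLUMNS)
        return cls(chrom_lengths=chrom_lengths, genes=genes, exons=exons)
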