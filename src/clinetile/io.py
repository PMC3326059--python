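"""File-format helpers: FASTA, GFF3 (gene/exon features), TSV tables, GMT categories.

FASTA goes through Biopython; GFF3 is handled by a light reader/writer that
supports exactly the gene/exon feature subset the pipeline produces and
consumes (1-based inclusive coordinates, ``ID``/``Parent`` attributes).
"""

from __future__ import annotations

import os
from typing import Dict, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

GFF_COLUMNS = [
    "seqid", "source", "type", "start", "end",
    "score", "strand", "phase", "attributes",
]


def read_fasta(path: str | os.PathLike) -> Dict[str, str]:
    """Load a FASTA file into a ``{name: sequence}`` dict (uppercased)."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(genome: Mapping[str, str], path: str | os.PathLike) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in genome.items()]
    SeqIO.write(records, str(path), "fasta")


def parse_gff_attributes(attr: str) -> Dict[str, str]:
    out: Dict[str, str] = {}
    for field in attr.strip().split(";"):
        field = field.strip()
        if not field:
            continue
        key, _, value = field.partition("=")
        out[key] = value
    return out


def read_gff3(path: str | os.PathLike) -> pd.DataFrame:
    """Read a GFF3 file into a DataFrame with ``GFF_COLUMNS`` (comments skipped)."""
    rows = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 9:
                raise ValueError(f"malformed GFF3 line: {line!r}")
            rows.append(parts)
    df = pd.DataFrame(rows, columns=GFF_COLUMNS)
    df["start"] = df["start"].astype(int)
    df["end"] = df["end"].astype(int)
    return df


def write_gff3(df: pd.DataFrame, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for row in df.itertuples(index=False):
            fh.write("\t".join(str(v) for v in row) + "\n")


def read_tsv(path: str | os.PathLike, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", **kwargs)


def write_tsv(df: pd.DataFrame, path: str | os.PathLike, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index)


def read_gmt(path: str | os.PathLike) -> Dict[str, list]:
    """Read GMT category definitions: ``name <TAB> description <TAB> member...``."""
    categories: Dict[str, list] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not parts[0]:
                continue
            categories[parts[0]] = [g for g in parts[2:] if g]
    return categories


def write_gmt(categories: Mapping[str, list], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for name, members in categories.items():
            fh.write("\t".join([name, "na", *members]) + "\n")
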