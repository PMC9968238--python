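"""Genomic file IO helpers: FASTA, FASTQ, GTF, BED6, TSV.

Conventions used across the package:

* internal coordinates are 0-based half-open;
* GTF is read and written 1-based closed;
* BED6 is 0-based half-open with strand in column 6;
* FASTA is written with 60-column wrapping;
* FASTQ is Phred+33.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass
from typing import Iterable, Iterator

import pandas as pd
from Bio import SeqIO
from Bio.SeqIO.QualityIO import FastqGeneralIterator

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string."""
    return seq.translate(_COMP)[::-1]


# ---------------------------------------------------------------------------
# FASTA

def write_fasta(records: Iterable[tuple[str, str]], width: int = 60) -> str:
    out = []
    for name, seq in records:
        out.append(f">{name}\n")
        for i in range(0, len(seq), width):
            out.append(seq[i : i + width] + "\n")
    return "".join(out)


def read_fasta(text_or_path: str) -> dict[str, str]:
    """Read FASTA from a path or from raw text (anything with a newline)."""
    if "\n" in text_or_path:
        handle = io.StringIO(text_or_path)
    else:
        handle = open(text_or_path)
    with handle:
        return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(handle, "fasta")}


# ---------------------------------------------------------------------------
# FASTQ

def write_fastq(records: Iterable[tuple[str, str]], qual_char: str = "I") -> str:
    out = []
    for name, seq in records:
        out.append(f"@{name}\n{seq}\n+\n{qual_char * len(seq)}\n")
    return "".join(out)


def read_fastq(text_or_path: str) -> list[tuple[str, str]]:
    """Return (read_id, sequence) pairs."""
    if "\n" in text_or_path:
        handle = io.StringIO(text_or_path)
    else:
        handle = open(text_or_path)
    with handle:
        return [(title.split()[0], seq) for title, seq, _ in FastqGeneralIterator(handle)]


# ---------------------------------------------------------------------------
# GTF

@dataclass
class GtfRecord:
    chrom: str
    source: str
    feature: str
    start: int  # 0-based half-open internally
    end: int
    strand: str
    attributes: dict[str, str]

    def to_line(self) -> str:
        attrs = " ".join(f'{k} "{v}";' for k, v in self.attributes.items())
        return (
            f"{self.chrom}\t{self.source}\t{self.feature}\t{self.start + 1}\t"
            f"{self.end}\t.\t{self.strand}\t.\t{attrs}"
        )


_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


def parse_gtf(text_or_path: str) -> list[GtfRecord]:
    if "\n" in text_or_path:
        lines = text_or_path.splitlines()
    else:
        with open(text_or_path) as fh:
            lines = fh.read().splitlines()
    records = []
    for lineno, line in enumerate(lines, 1):
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 9:
            raise ValueError(f"malformed GTF line {lineno}: expected 9 fields")
        try:
            start = int(fields[3]) - 1
            end = int(fields[4])
        except ValueError as exc:
            raise ValueError(f"malformed GTF line {lineno}: bad coordinates") from exc
        attrs = dict(_ATTR_RE.findall(fields[8]))
        records.append(
            GtfRecord(fields[0], fields[1], fields[2], start, end, fields[6], attrs)
        )
    return records


def write_gtf(records: Iterable[GtfRecord]) -> str:
    return "".join(rec.to_line() + "\n" for rec in records)


# ---------------------------------------------------------------------------
# BED6

BED6_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]


def read_bed6(text_or_path: str) -> pd.DataFrame:
    if isinstance(text_or_path, str) and "\n" in text_or_path:
        src = io.StringIO(text_or_path)
    else:
        src = text_or_path
    try:
        df = pd.read_csv(src, sep="\t", header=None, names=BED6_COLUMNS, comment="#")
    except pd.errors.EmptyDataError:
        df = pd.DataFrame(columns=BED6_COLUMNS)
    return df.astype({"start": int, "end": int}, errors="ignore")


def write_bed6(df: pd.DataFrame) -> str:
    return df.to_csv(sep="\t", header=False, index=False, columns=BED6_COLUMNS)


# ---------------------------------------------------------------------------
# TSV

def write_tsv(df: pd.DataFrame, path: str | None = None, index: bool = False) -> str:
    return df.to_csv(path, sep="\t", index=index)


def read_tsv(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
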