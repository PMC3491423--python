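"""Shared data types, coordinate conventions and file formats.

All genomic coordinates are 0-based, half-open ``[start, end)`` — BED's
native convention.  TSS tables are 0-based positions.  Two intervals
``[a, b)`` and ``[c, d)`` overlap iff ``a < d and c < b``.

Matrices travel as :class:`pandas.DataFrame` with unique row/column ids;
missing values are encoded as NA, never as 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

STAGES = {"1", "2", "3", "4", "4S"}
MYCN_STATES = {"amplified", "single_copy"}
OUTCOMES = {"alive", "dod"}


class FormatError(ValueError):
    """A file did not conform to its expected format."""


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int
    score: float | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:[{self.start}, {self.end})"
            )

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains(self, chrom: str, pos: int) -> bool:
        return self.chrom == chrom and self.start <= pos < self.end


@dataclass(frozen=True)
class PromoterAnnotation:
    """A gene's transcription start site (0-based) with strand."""

    gene: str
    chrom: str
    tss: int
    strand: str

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError(f"unknown strand {self.strand!r} for {self.gene}")


def promoter_window(
    p: PromoterAnnotation, upstream: int = 1500, downstream: int = 1000
) -> GenomicInterval:
    """Strand-aware promoter window around a TSS.

    ``upstream`` extends against the direction of transcription and
    ``downstream`` with it, so on the minus strand the window mirrors.
    The start is clipped at 0.
    """
    if upstream < 0 or downstream < 0:
        raise ValueError("window extents must be non-negative")
    if p.strand == "+":
        start, end = p.tss - upstream, p.tss + downstream
    else:
        start, end = p.tss - downstream, p.tss + upstream
    return GenomicInterval(p.chrom, max(start, 0), end)


# ---------------------------------------------------------------------------
# BED

def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read a 3-5 column BED file as 0-based half-open intervals."""
    intervals: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}: line {lineno}: fewer than 3 fields")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise FormatError(
                    f"{path}: line {lineno}: non-integer coordinate"
                ) from exc
            score = None
            if len(fields) >= 5 and fields[4] not in ("", "."):
                try:
                    score = float(fields[4])
                except ValueError as exc:
                    raise FormatError(
                        f"{path}: line {lineno}: non-numeric score"
                    ) from exc
            try:
                intervals.append(GenomicInterval(fields[0], start, end, score))
            except ValueError as exc:
                raise FormatError(f"{path}: line {lineno}: {exc}") from exc
    return intervals


def write_bed(intervals: Iterable[GenomicInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            name = f"peak{i + 1}"
            score = "." if iv.score is None else f"{iv.score:g}"
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{score}\n")


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: str | Path) -> dict[str, str]:
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise FormatError(f"{path}: duplicate sequence id {rec.id!r}")
        seqs[rec.id] = str(rec.seq).upper()
    return seqs


def write_fasta(seqs: dict[str, str], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()
    ]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# TSS annotation tables

def read_tss(path: str | Path) -> pd.DataFrame:
    """Read a TSS table (gene, chrom, tss, strand; 0-based positions)."""
    df = pd.read_csv(path, sep="\t", dtype={"gene": str, "chrom": str})
    missing = {"gene", "chrom", "tss", "strand"} - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    if df["gene"].duplicated().any():
        dup = df.loc[df["gene"].duplicated(), "gene"].iloc[0]
        raise FormatError(f"{path}: duplicate gene id {dup!r}")
    return df


def write_tss(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def tss_annotations(df: pd.DataFrame) -> list[PromoterAnnotation]:
    return [
        PromoterAnnotation(r.gene, r.chrom, int(r.tss), r.strand)
        for r in df.itertuples()
    ]


# ---------------------------------------------------------------------------
# Clinical tables

CLINICAL_COLUMNS = [
    "sample",
    "stage",
    "mycn",
    "age_days",
    "outcome",
    "followup_days",
    "relapse_days",
]


def validate_clinical(df: pd.DataFrame) -> pd.DataFrame:
    missing = set(CLINICAL_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"clinical table missing columns {sorted(missing)}")
    if df["sample"].duplicated().any():
        raise FormatError("duplicate sample ids in clinical table")
    bad = ~df["stage"].astype(str).isin(STAGES)
    if bad.any():
        raise FormatError(f"invalid stage values: {df.loc[bad, 'stage'].unique()}")
    if (~df["mycn"].isin(MYCN_STATES)).any():
        raise FormatError("invalid MYCN status")
    if (~df["outcome"].isin(OUTCOMES)).any():
        raise FormatError("invalid outcome")
    if (df["age_days"] < 0).any() or (df["followup_days"] < 0).any():
        raise FormatError("negative age or follow-up")
    return df


def read_clinical(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"sample": str, "stage": str})
    return validate_clinical(df)


def write_clinical(df: pd.DataFrame, path: str | Path) -> None:
    validate_clinical(df).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Labeled matrices

def read_matrix(path: str | Path, sep: str = "\t") -> pd.DataFrame:
    df = pd.read_csv(path, sep=sep, index_col=0)
    if df.index.duplicated().any():
        raise FormatError(f"{path}: duplicate row ids")
    if df.columns.duplicated().any():
        raise FormatError(f"{path}: duplicate column ids")
    return df


def write_matrix(df: pd.DataFrame, path: str | Path, sep: str = "\t") -> None:
    df.to_csv(path, sep=sep)
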