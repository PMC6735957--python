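"""Domain types for gene models plus readers/writers for the text formats.

Coordinates are GTF-style throughout: 1-based, inclusive on both ends.
BED-style inputs (SNPs, exclusion regions, per-base score tracks) are
converted to this convention on read.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GenomicInterval",
    "TranscriptModel",
    "ExpressionMatrix",
    "SampleTable",
    "GtfParseError",
    "read_gtf",
    "write_gtf",
    "transcript_length",
    "intron_chain",
    "locus_span",
    "read_expression_tsv",
    "write_expression_tsv",
    "read_sample_table",
    "read_bed_intervals",
    "read_bedgraph",
    "read_chrom_sizes",
]

VALID_STRANDS = ("+", "-", ".")


class GtfParseError(ValueError):
    """Raised when a GTF line cannot be parsed; message names the line number."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A closed genomic interval, 1-based inclusive."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 1:
            raise ValueError(f"start must be >= 1, got {self.start}")
        if self.end < self.start:
            raise ValueError(f"end ({self.end}) < start ({self.start})")
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"strand must be one of {VALID_STRANDS}, got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start + 1

    def overlap_length(self, other: "GenomicInterval") -> int:
        """Number of shared bases, ignoring strand. 0 if on different chroms."""
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start) + 1)

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )


@dataclass
class TranscriptModel:
    """A stranded, (multi-)exon transcript model.

    Exons must share one chromosome and strand, be sorted by start and be
    pairwise non-overlapping.
    """

    transcript_id: str
    gene_id: str
    exons: list[GenomicInterval]
    source: str = "assembled"
    biotype: str = "other"

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError(f"transcript {self.transcript_id!r} has no exons")
        chroms = {e.chrom for e in self.exons}
        strands = {e.strand for e in self.exons}
        if len(chroms) != 1:
            raise ValueError(f"transcript {self.transcript_id!r} spans chromosomes {sorted(chroms)}")
        if len(strands) != 1:
            raise ValueError(f"transcript {self.transcript_id!r} mixes strands {sorted(strands)}")
        if "." in strands:
            raise ValueError(f"transcript {self.transcript_id!r} must be stranded (+ or -)")
        self.exons = sorted(self.exons, key=lambda e: e.start)
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start <= a.end:
                raise ValueError(
                    f"transcript {self.transcript_id!r} has overlapping exons "
                    f"{a.start}-{a.end} and {b.start}-{b.end}"
                )

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    @property
    def start(self) -> int:
        return self.exons[0].start

    @property
    def end(self) -> int:
        return self.exons[-1].end


def transcript_length(t: TranscriptModel) -> int:
    """Total exonic length in nucleotides (sum of end - start + 1 over exons)."""
    return sum(len(e) for e in t.exons)


def intron_chain(t: TranscriptModel) -> list[GenomicInterval]:
    """Ordered introns (gaps between consecutive exons); empty for single-exon."""
    return [
        GenomicInterval(t.chrom, a.end + 1, b.start - 1, t.strand)
        for a, b in zip(t.exons, t.exons[1:])
    ]


def locus_span(t: TranscriptModel) -> GenomicInterval:
    """The transcript's full genomic span including introns."""
    return GenomicInterval(t.chrom, t.start, t.end, t.strand)


# --------------------------------------------------------------------------
# GTF I/O
# --------------------------------------------------------------------------

# accepts both `key "value";` (GTF) and `key=value;` (GFF-ish) attribute styles
_ATTR_RE = re.compile(r'\s*(\w+)\s*(?:=\s*|\s+)"?([^";]*?)"?\s*(?:;|$)')


def _parse_attributes(attr_field: str) -> dict[str, str]:
    return {m.group(1): m.group(2) for m in _ATTR_RE.finditer(attr_field)}


def read_gtf(path: str | Path) -> list[TranscriptModel]:
    """Parse exon features from a GTF file into TranscriptModel objects.

    Transcripts appear in order of first occurrence; exons are returned
    sorted by start. Raises :class:`GtfParseError` naming the offending line
    on malformed input.
    """
    exons_by_tx: dict[str, list[GenomicInterval]] = {}
    meta: dict[str, tuple[str, str]] = {}  # transcript_id -> (gene_id, source)
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise GtfParseError(
                    f"{path}: line {lineno}: expected 9 tab-separated fields, got {len(fields)}"
                )
            chrom, source, feature, start_s, end_s, _score, strand, _frame, attrs = fields
            if feature != "exon":
                continue
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise GtfParseError(f"{path}: line {lineno}: non-integer coordinates") from exc
            attributes = _parse_attributes(attrs)
            tx_id = attributes.get("transcript_id")
            gene_id = attributes.get("gene_id")
            if not tx_id or not gene_id:
                raise GtfParseError(
                    f"{path}: line {lineno}: exon lacks transcript_id/gene_id attributes"
                )
            try:
                interval = GenomicInterval(chrom, start, end, strand)
            except ValueError as exc:
                raise GtfParseError(f"{path}: line {lineno}: {exc}") from exc
            exons_by_tx.setdefault(tx_id, []).append(interval)
            meta.setdefault(tx_id, (gene_id, attributes.get("source", source)))
    models = []
    for tx_id, exons in exons_by_tx.items():
        gene_id, source = meta[tx_id]
        biotype = "other"
        models.append(
            TranscriptModel(tx_id, gene_id, exons, source=source, biotype=biotype)
        )
    return models


def write_gtf(models: Iterable[TranscriptModel], path: str | Path) -> None:
    """Write exon rows grouped by transcript, with canonical GTF quoting."""
    with open(path, "w") as fh:
        fh.write("##format: gtf\n")
        for t in models:
            for i, e in enumerate(t.exons, start=1):
                attrs = (
                    f'gene_id "{t.gene_id}"; transcript_id "{t.transcript_id}"; '
                    f'exon_number "{i}"; source "{t.source}";'
                )
                fh.write(
                    f"{e.chrom}\t{t.source}\texon\t{e.start}\t{e.end}\t.\t{e.strand}\t.\t{attrs}\n"
                )


# --------------------------------------------------------------------------
# Expression matrix / sample metadata
# --------------------------------------------------------------------------


class ExpressionMatrix:
    """Transcripts x samples FPKM matrix with unique labels and no negatives."""

    def __init__(self, values: pd.DataFrame):
        if values.index.has_duplicates:
            raise ValueError("duplicate transcript ids in expression matrix")
        if values.columns.has_duplicates:
            raise ValueError("duplicate sample ids in expression matrix")
        arr = values.to_numpy(dtype=float)
        if arr.size and np.nanmin(arr) < 0:
            raise ValueError("expression matrix contains negative values")
        self.values = values.astype(float)

    @property
    def transcript_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def row(self, transcript_id: str) -> pd.Series:
        return self.values.loc[transcript_id]

    def __eq__(self, other) -> bool:  # pragma: no cover - convenience
        return isinstance(other, ExpressionMatrix) and self.values.equals(other.values)


SAMPLE_REQUIRED_COLUMNS = (
    "sample_id",
    "individual_id",
    "tissue",
    "sex",
    "age",
    "race",
    "condition",
)
SAMPLE_OPTIONAL_COLUMNS = (
    "stage",
    "metastasis",
    "recurrence",
    "survival_time",
    "event",
)


class SampleTable:
    """Per-sample metadata: identity, demographics and optional clinical fields."""

    def __init__(self, table: pd.DataFrame):
        missing = [c for c in SAMPLE_REQUIRED_COLUMNS if c not in table.columns]
        if missing:
            raise ValueError(f"sample table missing required columns: {missing}")
        if table["sample_id"].duplicated().any():
            raise ValueError("sample_id values must be unique")
        if (table["age"].dropna() < 0).any():
            raise ValueError("age must be >= 0")
        if "survival_time" in table.columns:
            st = pd.to_numeric(table["survival_time"], errors="coerce")
            if (st.dropna() < 0).any():
                raise ValueError("survival_time must be >= 0")
        bad_cond = set(table["condition"].dropna()) - {"normal", "tumor"}
        if bad_cond:
            raise ValueError(f"condition must be 'normal' or 'tumor', got {sorted(bad_cond)}")
        self.table = table.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.table)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table["sample_id"])

    def subset(self, mask) -> "SampleTable":
        return SampleTable(self.table.loc[mask].reset_index(drop=True))


def read_expression_tsv(path: str | Path) -> ExpressionMatrix:
    """Read a TSV whose first column is transcript_id; remaining columns samples."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    return ExpressionMatrix(df)


def write_expression_tsv(m: ExpressionMatrix, path: str | Path) -> None:
    out = m.values.copy()
    out.index.name = "transcript_id"
    out.to_csv(path, sep="\t")


def read_sample_table(path: str | Path) -> SampleTable:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "individual_id": str})
    return SampleTable(df)


def read_bed_intervals(path: str | Path) -> list[GenomicInterval]:
    """Read BED (0-based half-open) intervals, converting to 1-based inclusive.

    Strand is taken from column 6 when present, else '.'.
    """
    out = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}: line {lineno}: BED needs >= 3 columns")
            chrom, start0, end0 = fields[0], int(fields[1]), int(fields[2])
            strand = fields[5] if len(fields) >= 6 and fields[5] in VALID_STRANDS else "."
            out.append(GenomicInterval(chrom, start0 + 1, end0, strand))
    return out


def read_bedgraph(path: str | Path) -> pd.DataFrame:
    """Read a bedGraph-style TSV (chrom, start0, end0, value) -> tidy frame.

    Coordinates converted to 1-based inclusive columns 'start' and 'end'.
    """
    df = pd.read_csv(
        path,
        sep="\t",
        comment="#",
        header=None,
        names=["chrom", "start0", "end0", "value"],
    )
    df["start"] = df["start0"] + 1
    df["end"] = df["end0"]
    return df[["chrom", "start", "end", "value"]]


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    """Read a two-column chrom sizes file into an ordered mapping."""
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            chrom, size = line.split()[:2]
            sizes[chrom] = int(size)
    return sizes
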