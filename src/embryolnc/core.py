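"""Shared genomic records and file I/O.

Coordinates are 0-based half-open internally; GTF is written and read as
1-based inclusive (pyranges converts on read). Exon lists are kept sorted
and non-overlapping.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import pyranges as pr

logger = logging.getLogger("embryolnc")

CODING = "protein_coding"
LNCRNA = "lncRNA"

__all__ = [
    "CODING",
    "LNCRNA",
    "GeneRecord",
    "TranscriptModel",
    "exonic_length",
    "merge_intervals",
    "write_gene_gtf",
    "write_transcript_gtf",
    "read_gene_gtf",
    "read_transcript_gtf",
    "write_expression",
    "read_expression",
    "write_sample_sheet",
    "read_sample_sheet",
]


def merge_intervals(ivs: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Merge overlapping/adjacent half-open intervals into a sorted disjoint list."""
    ivs = sorted(ivs)
    out: list[tuple[int, int]] = []
    for s, e in ivs:
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def exonic_length(exons: Sequence[tuple[int, int]]) -> int:
    return sum(e - s for s, e in exons)


@dataclass(frozen=True)
class GeneRecord:
    """A gene body with its exon structure and biotype."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    biotype: str
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be '+' or '-'")
        if not self.exons:
            raise ValueError(f"gene {self.gene_id}: needs at least one exon")


@dataclass(frozen=True)
class TranscriptModel:
    """A (possibly assembled) transcript: exon chain on a strand.

    ``length`` is the summed exonic length, not the genomic span.
    """

    transcript_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    source: str = "reference"
    gene_id: str = ""

    def __post_init__(self) -> None:
        ex = self.exons
        if not ex:
            raise ValueError(f"transcript {self.transcript_id}: needs >=1 exon")
        for (s1, e1), (s2, e2) in zip(ex, ex[1:]):
            if s2 < e1:
                raise ValueError(
                    f"transcript {self.transcript_id}: exons overlap or unsorted"
                )

    @property
    def length(self) -> int:
        return exonic_length(self.exons)

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def intron_chain(self) -> tuple[tuple[int, int], ...]:
        """Intron coordinates ((end_i, start_{i+1}), ...); empty for single-exon."""
        ex = self.exons
        return tuple((ex[i][1], ex[i + 1][0]) for i in range(len(ex) - 1))

    def with_id(self, transcript_id: str) -> "TranscriptModel":
        return replace(self, transcript_id=transcript_id)


# ---------------------------------------------------------------------------
# GTF
# ---------------------------------------------------------------------------

def _gtf_line(chrom, source, feature, start, end, strand, attrs: str) -> str:
    # internal half-open -> GTF 1-based inclusive
    return f"{chrom}\t{source}\t{feature}\t{start + 1}\t{end}\t.\t{strand}\t.\t{attrs}\n"


def write_gene_gtf(genes: Sequence[GeneRecord], path: str | Path,
                   source: str = "embryolnc") -> None:
    """Write genes with one transcript per gene and explicit exon features."""
    with open(path, "w") as fh:
        for g in sorted(genes, key=lambda g: (g.chrom, g.start, g.gene_id)):
            ga = f'gene_id "{g.gene_id}"; gene_biotype "{g.biotype}";'
            fh.write(_gtf_line(g.chrom, source, "gene", g.start, g.end, g.strand, ga))
            ta = f'gene_id "{g.gene_id}"; transcript_id "{g.gene_id}.t1"; gene_biotype "{g.biotype}";'
            fh.write(_gtf_line(g.chrom, source, "transcript", g.start, g.end, g.strand, ta))
            for s, e in g.exons:
                fh.write(_gtf_line(g.chrom, source, "exon", s, e, g.strand, ta))


def write_transcript_gtf(transcripts: Sequence[TranscriptModel], path: str | Path,
                         source: str | None = None) -> None:
    with open(path, "w") as fh:
        for t in sorted(transcripts, key=lambda t: (t.chrom, t.start, t.transcript_id)):
            src = source or t.source or "embryolnc"
            gid = t.gene_id or t.transcript_id
            attrs = f'gene_id "{gid}"; transcript_id "{t.transcript_id}";'
            fh.write(_gtf_line(t.chrom, src, "transcript", t.start, t.end, t.strand, attrs))
            for s, e in t.exons:
                fh.write(_gtf_line(t.chrom, src, "exon", s, e, t.strand, attrs))


def read_gene_gtf(path: str | Path) -> list[GeneRecord]:
    """Read a gene-level GTF (gene/exon features with gene_biotype) into records."""
    df = pr.read_gtf(str(path)).df
    genes = df[df.Feature == "gene"]
    exons = df[df.Feature == "exon"]
    out = []
    for row in genes.itertuples():
        ex = exons[exons.gene_id == row.gene_id]
        ivs = merge_intervals(zip(ex.Start.astype(int), ex.End.astype(int)))
        if not ivs:
            ivs = [(int(row.Start), int(row.End))]
        out.append(GeneRecord(
            gene_id=row.gene_id, chrom=str(row.Chromosome),
            start=int(row.Start), end=int(row.End), strand=str(row.Strand),
            biotype=str(getattr(row, "gene_biotype", CODING)),
            exons=tuple(ivs)))
    return out


def read_transcript_gtf(path: str | Path, source: str = "reference") -> list[TranscriptModel]:
    df = pr.read_gtf(str(path)).df
    exons = df[df.Feature == "exon"]
    if exons.empty:
        raise ValueError(f"{path}: no exon features found")
    out = []
    for (tid,), ex in exons.groupby(["transcript_id"], sort=True):
        ex = ex.sort_values("Start")
        out.append(TranscriptModel(
            transcript_id=str(tid), chrom=str(ex.Chromosome.iloc[0]),
            strand=str(ex.Strand.iloc[0]),
            exons=tuple((int(s), int(e)) for s, e in zip(ex.Start, ex.End)),
            source=source, gene_id=str(ex.gene_id.iloc[0])))
    return out


# ---------------------------------------------------------------------------
# Expression matrices and sample sheets (plain TSV)
# ---------------------------------------------------------------------------

def write_expression(matrix: pd.DataFrame, path: str | Path) -> None:
    matrix.to_csv(path, sep="\t", index_label="gene_id", float_format="%.6g")


def read_expression(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="gene_id")


def write_sample_sheet(sheet: pd.DataFrame, path: str | Path) -> None:
    sheet.to_csv(path, sep="\t", index=False)


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    sheet = pd.read_csv(path, sep="\t")
    missing = {"cell_id", "stage"} - set(sheet.columns)
    if missing:
        raise ValueError(f"sample sheet missing columns: {sorted(missing)}")
    return sheet
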