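"""Four-step novel-lncRNA detection pipeline.

1. Keep transcripts assembled by both assemblers (same chromosome, strand
   and identical intron chain; single-exon transcripts never match).
2. Remove transcripts with >=1 exon overlapping (>=1 bp, strand-agnostic)
   any annotated exon from any supplied annotation set.
3. Keep transcripts with summed exonic length > 200 bp and >=2 exons.
4. Keep transcripts called noncoding by the coding-potential consensus
   (default: all four tools agree noncoding; 'majority' = >=3).

Every input transcript receives exactly one audit entry: kept, or the first
stage that eliminated it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from intervaltree import IntervalTree

from .core import GeneRecord, TranscriptModel, logger, write_transcript_gtf

__all__ = [
    "PipelineReport",
    "intersect_assemblies",
    "remove_annotated_overlaps",
    "size_exon_filter",
    "coding_potential_consensus",
    "run_pipeline",
    "write_bed",
]

STAGES = ("intersect", "annotation_overlap", "size_exon", "coding_potential")


@dataclass
class PipelineReport:
    counts: dict[str, int] = field(default_factory=dict)
    audit: dict[str, str] = field(default_factory=dict)  # tid -> kept | stage name

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(sorted(self.audit.items()),
                            columns=["transcript_id", "outcome"])


def _chain_key(t: TranscriptModel):
    return (t.chrom, t.strand, t.intron_chain)


def intersect_assemblies(
    set_a: list[TranscriptModel], set_b: list[TranscriptModel],
) -> list[TranscriptModel]:
    """A-transcripts whose (chrom, strand, intron chain) matches some B-transcript.

    Terminal exon ends may differ; A's coordinates are kept. Single-exon
    transcripts have an empty intron chain and are never matched.
    """
    if not set_a or not set_b:
        logger.warning("intersect_assemblies: empty input set")
        return []
    b_chains = {_chain_key(t) for t in set_b if len(t.exons) >= 2}
    return [t for t in set_a if len(t.exons) >= 2 and _chain_key(t) in b_chains]


def _exon_trees(annotation_sets) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for ann in annotation_sets:
        for rec in ann:
            tree = trees.setdefault(rec.chrom, IntervalTree())
            for s, e in rec.exons:
                tree.addi(s, e)
    return trees


def remove_annotated_overlaps(
    transcripts: list[TranscriptModel],
    annotations: list[list[GeneRecord]] | list[list[TranscriptModel]],
) -> list[TranscriptModel]:
    """Drop transcripts with any exon overlapping any annotated exon.

    Overlap is >=1 bp and strand-agnostic; a transcript lying entirely inside
    an annotated intron is retained.
    """
    trees = _exon_trees(annotations)
    kept = []
    for t in transcripts:
        tree = trees.get(t.chrom)
        if tree is None or not any(tree.overlap(s, e) for s, e in t.exons):
            kept.append(t)
    return kept


def size_exon_filter(
    transcripts: list[TranscriptModel],
    min_length: int = 200,
    min_exons: int = 2,
) -> list[TranscriptModel]:
    """Keep transcripts with exonic length strictly > min_length and >= min_exons exons."""
    return [t for t in transcripts
            if t.length > min_length and len(t.exons) >= min_exons]


def coding_potential_consensus(
    transcripts: list[TranscriptModel],
    calls: pd.DataFrame,
    rule: str = "all",
) -> list[TranscriptModel]:
    """Keep transcripts the tool panel agrees are noncoding.

    ``calls`` has a transcript_id column plus one column per tool with values
    'coding'/'noncoding'. rule='all' keeps rows where every tool says
    noncoding; rule='majority' keeps rows with >=3 noncoding calls.
    """
    if rule not in ("all", "majority"):
        raise ValueError(f"unknown consensus rule {rule!r}")
    table = calls.set_index("transcript_id")
    tools = list(table.columns)
    kept = []
    for t in transcripts:
        if t.transcript_id not in table.index:
            raise KeyError(f"no coding-potential calls for {t.transcript_id}")
        row = table.loc[t.transcript_id]
        missing = [c for c in tools if pd.isna(row[c])]
        if missing:
            raise ValueError(
                f"missing call for {t.transcript_id} in column(s) {missing}")
        n_nc = sum(row[c] == "noncoding" for c in tools)
        need = len(tools) if rule == "all" else 3
        if n_nc >= need:
            kept.append(t)
    return kept


def run_pipeline(
    set_a: list[TranscriptModel],
    set_b: list[TranscriptModel],
    annotations,
    calls: pd.DataFrame,
    min_length: int = 200,
    min_exons: int = 2,
    rule: str = "all",
) -> tuple[list[TranscriptModel], PipelineReport]:
    """Apply the four stages in order and record the full audit trail."""
    report = PipelineReport()
    report.counts["input_A"] = len(set_a)
    report.counts["input_B"] = len(set_b)

    s1 = intersect_assemblies(set_a, set_b)
    survivors = {t.transcript_id for t in s1}
    for t in set_a:
        if t.transcript_id not in survivors:
            report.audit[t.transcript_id] = "intersect"
    report.counts["intersected"] = len(s1)

    s2 = remove_annotated_overlaps(s1, annotations)
    survivors = {t.transcript_id for t in s2}
    for t in s1:
        if t.transcript_id not in survivors:
            report.audit[t.transcript_id] = "annotation_overlap"
    report.counts["unannotated"] = len(s2)

    s3 = size_exon_filter(s2, min_length=min_length, min_exons=min_exons)
    survivors = {t.transcript_id for t in s3}
    for t in s2:
        if t.transcript_id not in survivors:
            report.audit[t.transcript_id] = "size_exon"
    report.counts["size_exon_pass"] = len(s3)

    s4 = coding_potential_consensus(s3, calls, rule=rule)
    survivors = {t.transcript_id for t in s4}
    for t in s3:
        if t.transcript_id not in survivors:
            report.audit[t.transcript_id] = "coding_potential"
    for t in s4:
        report.audit[t.transcript_id] = "kept"
    report.counts["novel_lncrna"] = len(s4)
    return sorted(s4, key=lambda t: t.transcript_id), report


def write_bed(transcripts: list[TranscriptModel], path: str | Path) -> None:
    """BED12-lite output (0-based half-open) for the novel set."""
    with open(path, "w") as fh:
        for t in sorted(transcripts, key=lambda t: (t.chrom, t.start)):
            sizes = ",".join(str(e - s) for s, e in t.exons)
            starts = ",".join(str(s - t.start) for s, _ in t.exons)
            fh.write(f"{t.chrom}\t{t.start}\t{t.end}\t{t.transcript_id}\t0\t"
                     f"{t.strand}\t{t.start}\t{t.end}\t0\t{len(t.exons)}\t"
                     f"{sizes}\t{starts}\n")


def write_novel_outputs(transcripts, report: PipelineReport, outdir: str | Path):
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_transcript_gtf(transcripts, outdir / "novel_lncrna.gtf")
    write_bed(transcripts, outdir / "novel_lncrna.bed")
    report.to_frame().to_csv(outdir / "pipeline_audit.tsv", sep="\t", index=False)
    pd.Series(report.counts).to_csv(outdir / "pipeline_counts.tsv", sep="\t",
                                    header=False)
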