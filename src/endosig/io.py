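"""Readers and writers for the plain-text formats the pipeline exchanges.

BED (0-based half-open; 3 columns for a plain region set, a 4th label
column for annotation tracks), tab-separated count/expression matrices,
sample sheets, chromosome-size tables, FASTA sequence sets and JASPAR PFM
matrices. All tables are tab-separated with '.' for missing values.
"""
from __future__ import annotations

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .diffbind import RegionCounts, SampleDesign
from .expression import ExpressionMatrix
from .intervals import GenomicInterval, RegionSet
from .overlap import AnnotationTrack

__all__ = [
    "read_bed",
    "write_bed",
    "read_annotation_bed",
    "write_annotation_bed",
    "read_chrom_sizes",
    "write_chrom_sizes",
    "read_region_counts",
    "write_region_counts",
    "read_expression",
    "write_expression",
    "read_fasta",
    "write_fasta",
    "write_table",
]

MISSING = "."
FLOAT_FORMAT = "%.10g"


def _parse_bed_rows(path: str) -> list[tuple[str, int, int, str | None]]:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: fewer than 3 BED columns")
            chrom = parts[0]
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError:
                raise ValueError(
                    f"{path}:{lineno}: non-numeric coordinates {parts[1]!r}/{parts[2]!r}"
                ) from None
            if start >= end or start < 0:
                raise ValueError(
                    f"{path}:{lineno}: invalid interval {chrom}:{start}-{end}"
                )
            label = parts[3] if len(parts) > 3 else None
            rows.append((chrom, start, end, label))
    return rows


def read_bed(path: str, name: str | None = None) -> RegionSet:
    """Read a BED file as a :class:`RegionSet` (labels, if any, ignored)."""
    rows = _parse_bed_rows(path)
    return RegionSet(
        (GenomicInterval(c, s, e) for c, s, e, _ in rows),
        name=name if name is not None else path,
    )


def write_bed(rs: RegionSet, path: str) -> None:
    with open(path, "w") as fh:
        for iv in rs:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


def read_annotation_bed(path: str, name: str | None = None) -> AnnotationTrack:
    """Read a BED4 file as an annotation track, grouping by the label
    column."""
    rows = _parse_bed_rows(path)
    by_label: dict[str, list[GenomicInterval]] = {}
    for c, s, e, label in rows:
        if not label:
            raise ValueError(f"{path}: annotation BED requires a 4th label column")
        by_label.setdefault(label, []).append(GenomicInterval(c, s, e))
    return AnnotationTrack(
        name=name if name is not None else path,
        by_label={lab: RegionSet(ivs, name=lab) for lab, ivs in by_label.items()},
    )


def write_annotation_bed(track: AnnotationTrack, path: str) -> None:
    rows = [
        (iv.chrom, iv.start, iv.end, lab)
        for lab in track.labels
        for iv in track.by_label[lab]
    ]
    rows.sort()
    with open(path, "w") as fh:
        for chrom, start, end, lab in rows:
            fh.write(f"{chrom}\t{start}\t{end}\t{lab}\n")


def read_chrom_sizes(path: str) -> dict[str, int]:
    sizes = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            chrom, size = line.split("\t")[:2]
            sizes[chrom] = int(size)
    return sizes


def write_chrom_sizes(sizes: dict[str, int], path: str) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(sizes):
            fh.write(f"{chrom}\t{sizes[chrom]}\n")


def write_region_counts(rc: RegionCounts, counts_path: str, sheet_path: str) -> None:
    """Write the counts matrix (region id index, sample header) and the
    sample sheet."""
    ids = [f"{iv.chrom}:{iv.start}-{iv.end}" for iv in rc.regions]
    df = pd.DataFrame(
        rc.counts, index=pd.Index(ids, name="region"), columns=rc.design.frame["sample"]
    )
    df.to_csv(counts_path, sep="\t")
    rc.design.frame.to_csv(sheet_path, sep="\t", index=False)


def read_region_counts(counts_path: str, sheet_path: str) -> RegionCounts:
    df = pd.read_csv(counts_path, sep="\t", index_col=0)
    sheet = pd.read_csv(sheet_path, sep="\t")
    design = SampleDesign(sheet)
    order = [str(s) for s in design.frame["sample"]]
    df = df[order]
    intervals = []
    for rid in df.index:
        chrom, _, span = str(rid).partition(":")
        start, _, end = span.partition("-")
        intervals.append(GenomicInterval(chrom, int(start), int(end)))
    return RegionCounts(
        regions=RegionSet(intervals, name=counts_path),
        counts=df.to_numpy(),
        design=design,
    )


def write_expression(expr: ExpressionMatrix, values_path: str, groups_path: str) -> None:
    expr.values.rename_axis("gene").to_csv(
        values_path, sep="\t", float_format=FLOAT_FORMAT
    )
    expr.groups.rename_axis("sample").rename("group").to_csv(groups_path, sep="\t")


def read_expression(values_path: str, groups_path: str) -> ExpressionMatrix:
    values = pd.read_csv(values_path, sep="\t", index_col=0)
    groups = pd.read_csv(groups_path, sep="\t", index_col=0)["group"]
    return ExpressionMatrix(values=values, groups=groups)


def read_fasta(path: str) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(path, "fasta")}


def write_fasta(seqs: dict[str, str], path: str) -> None:
    records = [SeqRecord(Seq(s), id=sid, description="") for sid, s in seqs.items()]
    SeqIO.write(records, path, "fasta")


def write_table(df: pd.DataFrame, path: str, index: bool = False) -> None:
    """Write a result table: tab-separated, '.' for missing, stable float
    format."""
    df.to_csv(path, sep="\t", index=index, na_rep=MISSING, float_format=FLOAT_FORMAT)
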