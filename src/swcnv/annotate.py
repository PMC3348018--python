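"""Known/novel classification of CNV segments against catalogue tables.

Detected segments are compared with previously reported structural-variant
records (a Database-of-Genomic-Variants-style table) by genomic overlap: a
segment is *known* when at least one record on the same chromosome overlaps
it with reciprocal overlap at or above a user threshold (threshold 0 means
any single shared base pair suffices), and *novel* otherwise.  Known-SNP
(dbSNP-style) records can additionally be listed for a locus range.

Catalogue files are local TSVs with a header; coordinates in the files are
1-based inclusive and converted to half-open internally.  Chromosome labels
are compared verbatim and case-sensitively.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Sequence

from intervaltree import IntervalTree

from .cnv_detect import CnvSegment
from .errors import ParseError, ValidationError

KNOWN = "known"
NOVEL = "novel"

DGV_REQUIRED = ("variant_id", "chrom", "start", "end", "variation_type")
SNP_REQUIRED = ("rsid", "chrom", "pos", "alleles")

#: variation_type spellings accepted as equivalent to a gain or a loss;
#: unlisted types (e.g. "cnv", "complex") are treated as compatible with both.
_TYPE_SYNONYMS = {
    "gain": "gain", "duplication": "gain", "dup": "gain", "insertion": "gain",
    "amplification": "gain",
    "loss": "loss", "deletion": "loss", "del": "loss",
}


@dataclass(frozen=True)
class DgvRecord:
    """A previously reported structural-variant region."""

    variant_id: str
    chrom: str
    start: int  # 1-based inclusive
    end: int
    variation_type: str
    genes: str | None = None
    reference: str | None = None
    attributes: tuple[tuple[str, str], ...] = ()

    def __post_init__(self):
        if self.start > self.end:
            raise ValidationError(
                f"record {self.variant_id!r}: start {self.start} > end {self.end}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class SnpRecord:
    """A catalogued SNP position."""

    rsid: str
    chrom: str
    pos: int  # 1-based
    alleles: str

    def __post_init__(self):
        if self.pos < 1:
            raise ValidationError(f"record {self.rsid!r}: pos {self.pos} < 1")


@dataclass(frozen=True)
class AnnotationHit:
    """A qualifying overlap between a detected segment and a known record."""

    segment: CnvSegment
    record: DgvRecord
    overlap_bp: int
    reciprocal_overlap: float


def _open(source) -> tuple[IO[str], bool]:
    if isinstance(source, (str, Path)):
        return open(source, encoding="utf-8", newline=""), True
    return source, False


def _read_table(source, required: Sequence[str], label: str):
    stream, should_close = _open(source)
    try:
        reader = csv.reader(stream, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise ParseError(f"empty {label} file") from None
        for col in required:
            if col not in header:
                raise ParseError(f"{label} file is missing required column {col!r}")
        idx = {c: header.index(c) for c in header}
        rows = []
        for lineno, fields in enumerate(reader, start=2):
            if not fields or all(f.strip() == "" for f in fields):
                continue
            if len(fields) != len(header):
                raise ParseError(
                    f"expected {len(header)} columns, found {len(fields)}", line=lineno
                )
            rows.append((lineno, {c: fields[i] for c, i in idx.items()}))
        return header, rows
    finally:
        if should_close:
            stream.close()


def parse_dgv(source) -> list[DgvRecord]:
    """Parse a DGV-style TSV; extra columns are kept as record attributes."""
    header, rows = _read_table(source, DGV_REQUIRED, "DGV")
    extra_cols = [c for c in header if c not in DGV_REQUIRED + ("genes", "reference")]
    records = []
    for lineno, row in rows:
        try:
            start, end = int(row["start"]), int(row["end"])
        except ValueError:
            raise ParseError(
                f"non-integer coordinates {row['start']!r}/{row['end']!r}", line=lineno
            ) from None
        try:
            records.append(DgvRecord(
                variant_id=row["variant_id"], chrom=row["chrom"], start=start, end=end,
                variation_type=row["variation_type"],
                genes=row.get("genes") or None, reference=row.get("reference") or None,
                attributes=tuple((c, row[c]) for c in extra_cols),
            ))
        except ValidationError as exc:
            raise ParseError(str(exc), line=lineno) from None
    records.sort(key=lambda r: (r.chrom, r.start, r.end, r.variant_id))
    return records


def parse_dbsnp(source) -> list[SnpRecord]:
    """Parse a dbSNP-style TSV (rsid, chrom, pos, alleles)."""
    _, rows = _read_table(source, SNP_REQUIRED, "dbSNP")
    records = []
    for lineno, row in rows:
        try:
            pos = int(row["pos"])
        except ValueError:
            raise ParseError(f"non-integer pos {row['pos']!r}", line=lineno) from None
        try:
            records.append(SnpRecord(row["rsid"], row["chrom"], pos, row["alleles"]))
        except ValidationError as exc:
            raise ParseError(str(exc), line=lineno) from None
    records.sort(key=lambda r: (r.chrom, r.pos, r.rsid))
    return records


def reciprocal_overlap(a_start: int, a_end: int, b_start: int, b_end: int) -> float:
    """min(overlap/len(a), overlap/len(b)) on 1-based inclusive intervals."""
    ov = min(a_end, b_end) - max(a_start, b_start) + 1
    if ov <= 0:
        return 0.0
    return min(ov / (a_end - a_start + 1), ov / (b_end - b_start + 1))


def _types_compatible(segment_type: str, variation_type: str) -> bool:
    mapped = _TYPE_SYNONYMS.get(variation_type.strip().lower())
    return mapped is None or mapped == segment_type


def annotate_segments(
    segments: Iterable[CnvSegment],
    dgv: Sequence[DgvRecord],
    min_reciprocal: float = 0.0,
    match_type: bool = False,
) -> tuple[list[AnnotationHit], list[str]]:
    """Classify each segment as known or novel against the catalogue.

    A segment is ``known`` iff some same-chromosome record overlaps it by at
    least 1 bp with reciprocal overlap >= ``min_reciprocal``; with
    ``match_type`` the record's variation type must also be compatible with
    the segment's direction.  Hits are returned sorted by descending
    overlap_bp then variant_id; statuses parallel the input segment order and
    are also written onto ``segment.known_status``.
    """
    if not 0.0 <= min_reciprocal <= 1.0:
        raise ValidationError("min_reciprocal must be in [0, 1]")
    trees: dict[str, IntervalTree] = {}
    for rec in dgv:
        # half-open interval keys
        trees.setdefault(rec.chrom, IntervalTree())[rec.start - 1:rec.end] = rec

    segments = list(segments)
    hits: list[AnnotationHit] = []
    statuses: list[str] = []
    for seg in segments:
        seg_hits: list[AnnotationHit] = []
        tree = trees.get(seg.chrom)
        if tree is not None:
            for iv in tree.overlap(seg.start - 1, seg.end):
                rec: DgvRecord = iv.data
                if match_type and not _types_compatible(seg.type, rec.variation_type):
                    continue
                ov = min(seg.end, rec.end) - max(seg.start, rec.start) + 1
                rec_ro = reciprocal_overlap(seg.start, seg.end, rec.start, rec.end)
                if ov >= 1 and rec_ro >= min_reciprocal:
                    seg_hits.append(AnnotationHit(seg, rec, ov, rec_ro))
        seg_hits.sort(key=lambda h: (-h.overlap_bp, h.record.variant_id))
        status = KNOWN if seg_hits else NOVEL
        seg.known_status = status
        statuses.append(status)
        hits.extend(seg_hits)
    return hits, statuses


def snps_in_range(
    snps: Sequence[SnpRecord], chrom: str, start: int, end: int
) -> list[SnpRecord]:
    """Catalogued SNPs with position in [start, end] on chrom, sorted by position."""
    if start > end:
        raise ValidationError(f"range start {start} > end {end}")
    out = [r for r in snps if r.chrom == chrom and start <= r.pos <= end]
    out.sort(key=lambda r: (r.pos, r.rsid))
    return out
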