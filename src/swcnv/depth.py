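"""Per-locus read depth, allele frequencies and SNP comparison from alignments.

The pileup walks each read's CIGAR once and accumulates, for every reference
position in the queried window, how many reads contribute an A/C/G/T/N base
or a deletion (CIGAR ``D``) there.  A read contributes at most one count per
column; insertions never create columns; reference skips (``N`` ops) add
nothing.  Depth at a column is the sum of its counts, by construction.

On top of the pileup sit a frequency-threshold SNP caller (the most frequent
non-reference substitution with sufficient depth and allele fraction — no
genotype-likelihood model), a low-depth run scanner for homozygous-deletion
candidates, and a two-sample SNP comparison that reports runs of consecutive
differing sites as copy-number candidate regions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pysam
from pyfaidx import Fasta

from .acgh_io import chrom_sort_key
from .errors import ValidationError

BASES = ("A", "C", "G", "T", "N", "DEL")
EXCLUDE_CATEGORIES = frozenset({"unmapped", "secondary", "duplicate", "qc_fail"})


@dataclass(frozen=True)
class DepthParams:
    """Read/base filters for the pileup.

    Defaults are permissive (mapq/baseq 0) apart from excluding unmapped,
    secondary, duplicate and QC-fail records, so raw counts are reproducible
    without opinionated filtering.
    """

    min_mapq: int = 0
    min_baseq: int = 0
    exclude: frozenset[str] = EXCLUDE_CATEGORIES

    def __post_init__(self):
        if self.min_mapq < 0 or self.min_baseq < 0:
            raise ValidationError("min_mapq and min_baseq must be >= 0")
        unknown = set(self.exclude) - EXCLUDE_CATEGORIES
        if unknown:
            raise ValidationError(f"unknown exclude categories {sorted(unknown)}")


@dataclass
class PileupColumn:
    """Counts of aligned bases and deletions at one reference position."""

    chrom: str
    pos: int  # 1-based
    counts: dict[str, int]
    ref_base: str | None = None

    @property
    def depth(self) -> int:
        return sum(self.counts.values())

    @property
    def base_depth(self) -> int:
        """Reads contributing an aligned base (deletion ops excluded).

        This is the sequence-coverage signal: inside a homozygous deletion it
        drops to ~0 even when deletion-spanning reads keep ``depth`` non-zero
        through their ``DEL`` counts.
        """
        return self.depth - self.counts.get("DEL", 0)


@dataclass(frozen=True)
class VariantCall:
    """A frequency-threshold SNP call at one locus of one sample."""

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    depth: int
    alt_fraction: float
    sample: str

    def __post_init__(self):
        if self.alt == self.ref:
            raise ValidationError("alt equals ref")
        if not 0.0 < self.alt_fraction <= 1.0:
            raise ValidationError(f"alt_fraction {self.alt_fraction} outside (0, 1]")


def _should_skip(read: pysam.AlignedSegment, params: DepthParams) -> bool:
    if "unmapped" in params.exclude and read.is_unmapped:
        return True
    if read.is_unmapped:  # no coordinates to pile up either way
        return True
    if "secondary" in params.exclude and read.is_secondary:
        return True
    if "duplicate" in params.exclude and read.is_duplicate:
        return True
    if "qc_fail" in params.exclude and read.is_qcfail:
        return True
    return read.mapping_quality < params.min_mapq


def _iter_region_reads(af: pysam.AlignmentFile, chrom: str, start0: int, end0: int):
    """Reads overlapping [start0, end0); uses the index when one exists."""
    if af.has_index():
        yield from af.fetch(chrom, start0, end0)
        return
    tid = af.get_tid(chrom)
    for read in af.fetch(until_eof=True):
        if read.is_unmapped or read.reference_id != tid:
            continue
        if read.reference_start < end0 and read.reference_end is not None \
                and read.reference_end > start0:
            yield read


def pileup(
    alignments,
    chrom: str,
    start: int,
    end: int,
    params: DepthParams = DepthParams(),
    reference=None,
) -> list[PileupColumn]:
    """One :class:`PileupColumn` per reference position in [start, end] (1-based).

    ``alignments`` is a SAM/BAM path or an open ``pysam.AlignmentFile``; plain
    SAM without an index is scanned sequentially.  When ``reference`` (FASTA
    path, ``pyfaidx.Fasta`` or chrom->sequence mapping) is given, each
    column's ``ref_base`` is filled in.
    """
    if start > end:
        raise ValidationError(f"region start {start} > end {end}")
    if start < 1:
        raise ValidationError("region start must be >= 1")
    close = False
    if isinstance(alignments, (str, Path)):
        af = pysam.AlignmentFile(str(alignments), require_index=False)
        close = True
    else:
        af = alignments
    try:
        if chrom not in af.references:
            raise ValidationError(
                f"reference sequence {chrom!r} not present in alignment header"
            )
        start0, end0 = start - 1, end
        n = end0 - start0
        cols = [dict.fromkeys(BASES, 0) for _ in range(n)]
        for read in _iter_region_reads(af, chrom, start0, end0):
            if _should_skip(read, params):
                continue
            _accumulate(read, start0, end0, cols, params.min_baseq)
    finally:
        if close:
            af.close()

    ref_seq = _load_reference(reference, chrom, start, end) if reference is not None else None
    out = []
    for i, counts in enumerate(cols):
        out.append(PileupColumn(
            chrom=chrom,
            pos=start + i,
            counts={b: c for b, c in counts.items()},
            ref_base=ref_seq[i] if ref_seq is not None else None,
        ))
    return out


def _accumulate(read, start0: int, end0: int, cols, min_baseq: int) -> None:
    seq = read.query_sequence
    quals = read.query_qualities
    rp = read.reference_start
    qp = 0
    for op, length in read.cigartuples or ():
        if op in (0, 7, 8):  # M, =, X: consume both
            for k in range(length):
                pos = rp + k
                if start0 <= pos < end0:
                    if quals is not None and quals[qp + k] < min_baseq:
                        continue
                    base = seq[qp + k].upper() if seq else "N"
                    cols[pos - start0][base if base in "ACGT" else "N"] += 1
            rp += length
            qp += length
        elif op == 2:  # D: deletion on the reference
            for k in range(length):
                pos = rp + k
                if start0 <= pos < end0:
                    cols[pos - start0]["DEL"] += 1
            rp += length
        elif op == 3:  # N: reference skip, contributes nothing
            rp += length
        elif op in (1, 4):  # I, S consume the query only
            qp += length
        # H, P consume neither


def _load_reference(reference, chrom: str, start: int, end: int) -> str:
    if isinstance(reference, Mapping):
        seq = reference.get(chrom)
        if seq is None:
            raise ValidationError(f"reference has no sequence {chrom!r}")
    elif isinstance(reference, (str, Path)):
        seq = str(Fasta(str(reference))[chrom][:])
    else:  # assume pyfaidx.Fasta-like
        try:
            seq = str(reference[chrom][:])
        except KeyError:
            raise ValidationError(f"reference has no sequence {chrom!r}") from None
    if len(seq) < end:
        raise ValidationError(
            f"reference {chrom!r} length {len(seq)} shorter than region end {end}"
        )
    return seq[start - 1:end].upper()


def allele_frequency(column: PileupColumn) -> dict[str, float]:
    """Per-base fractions of the column's depth (only bases actually seen)."""
    depth = column.depth
    if depth < 1:
        raise ValidationError(f"allele_frequency at depth 0 ({column.chrom}:{column.pos})")
    return {b: c / depth for b, c in column.counts.items() if c > 0}


def call_snps(
    columns: Iterable[PileupColumn],
    reference,
    min_depth: int = 5,
    min_alt_fraction: float = 0.2,
    sample: str = "sample",
) -> list[VariantCall]:
    """Frequency-threshold SNP calls over pileup columns.

    At each column with depth >= ``min_depth``, the most frequent
    non-reference substitution base (N and deletions never qualify) is called
    when its fraction of the depth is >= ``min_alt_fraction``; ties between
    alt bases break by count then alphabetically.  At most one call per
    position.
    """
    if not 0.0 < min_alt_fraction <= 1.0:
        raise ValidationError("min_alt_fraction must be in (0, 1]")
    calls = []
    ref_cache: dict[tuple[str, int, int], str] = {}
    cols = list(columns)
    if not cols:
        return []
    # resolve reference once per chromosome over the spanned range
    for col in cols:
        depth = col.depth
        if depth < min_depth:
            continue
        ref_base = col.ref_base
        if ref_base is None:
            key = (col.chrom, col.pos, col.pos)
            if key not in ref_cache:
                ref_cache[key] = _load_reference(reference, col.chrom, col.pos, col.pos)
            ref_base = ref_cache[key]
        ref_base = ref_base.upper()
        candidates = [
            (b, col.counts.get(b, 0))
            for b in ("A", "C", "G", "T")
            if b != ref_base and col.counts.get(b, 0) > 0
        ]
        if not candidates:
            continue
        alt, count = min(candidates, key=lambda bc: (-bc[1], bc[0]))
        fraction = count / depth
        if fraction >= min_alt_fraction:
            calls.append(VariantCall(
                chrom=col.chrom, pos=col.pos, ref=ref_base, alt=alt,
                depth=depth, alt_fraction=fraction, sample=sample,
            ))
    return calls


def depth_deletion_scan(
    columns: Sequence[PileupColumn], depth_floor: int, min_span: int
) -> list[tuple[str, int, int, float]]:
    """Maximal runs of contiguous positions with base coverage <= ``depth_floor``.

    Runs shorter than ``min_span`` bp are dropped.  Columns must be a single
    contiguous window (as produced by :func:`pileup`).  The scan uses
    ``base_depth`` (aligned bases only): a deletion-spanning read marks a
    position via its ``DEL`` count but provides no sequence there, and low
    base coverage is the classic read-depth signature of a homozygous
    deletion.  Reported mean depth is likewise the mean base coverage.
    """
    cols = list(columns)
    for prev, cur in zip(cols, cols[1:]):
        if cur.chrom != prev.chrom or cur.pos != prev.pos + 1:
            raise ValidationError("depth_deletion_scan requires contiguous columns")
    out: list[tuple[str, int, int, float]] = []
    run: list[PileupColumn] = []
    for col in cols + [None]:  # sentinel flush
        if col is not None and col.base_depth <= depth_floor:
            run.append(col)
            continue
        if run and run[-1].pos - run[0].pos + 1 >= min_span:
            mean_depth = sum(c.base_depth for c in run) / len(run)
            out.append((run[0].chrom, run[0].pos, run[-1].pos, mean_depth))
        run = []
    return out


@dataclass(frozen=True)
class SiteDifference:
    """One position where two samples' SNP calls disagree."""

    chrom: str
    pos: int
    alt_a: str | None  # None: no call in that sample
    alt_b: str | None


@dataclass(frozen=True)
class CandidateRegion:
    """A run of consecutive differing SNP sites, a copy-number candidate."""

    chrom: str
    start: int
    end: int
    n_sites: int


def compare_samples(
    calls_a: Iterable[VariantCall],
    calls_b: Iterable[VariantCall],
    window_snps: int = 3,
) -> tuple[list[SiteDifference], list[CandidateRegion]]:
    """Site-level SNP differences between two samples and their clustered runs.

    A site differs when it is called in exactly one sample, or in both with
    different alternate alleles.  Candidate regions are maximal runs of at
    least ``window_snps`` consecutive differing sites, where "consecutive"
    means adjacent in the merged, position-sorted list of all sites called in
    either sample; a shared identical call breaks a run.
    """
    if window_snps < 1:
        raise ValidationError("window_snps must be >= 1")
    a = {(c.chrom, c.pos): c.alt for c in calls_a}
    b = {(c.chrom, c.pos): c.alt for c in calls_b}
    sites = sorted(set(a) | set(b), key=lambda s: (chrom_sort_key(s[0]), s[1]))

    diffs: list[SiteDifference] = []
    regions: list[CandidateRegion] = []
    run: list[tuple[str, int]] = []

    def flush():
        if len(run) >= window_snps:
            regions.append(CandidateRegion(run[0][0], run[0][1], run[-1][1], len(run)))
        run.clear()

    prev_chrom = None
    for site in sites:
        chrom, pos = site
        if chrom != prev_chrom:
            flush()
            prev_chrom = chrom
        alt_a, alt_b = a.get(site), b.get(site)
        if alt_a != alt_b:
            diffs.append(SiteDifference(chrom, pos, alt_a, alt_b))
            run.append(site)
        else:
            flush()
    flush()
    return diffs, regions
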