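"""Reading and writing the tab-delimited aCGH table and related flat files.

The aCGH format is one probe per row: ``probe_id``, ``probe_name``, ``chrom``,
``start``, ``end`` (1-based inclusive bp), followed by one log2-ratio column
per sample.  An optional header row names the samples in columns 6+.  Parsed
datasets are canonicalized: probes sorted within each chromosome by
(start, end, probe_id), chromosomes in natural order, so that any row
permutation of the same file parses to an identical dataset.

Coordinates are 1-based inclusive in every file this module touches; all
interval arithmetic elsewhere in the package is 0-based half-open and
conversion happens here, at the I/O boundary.
"""

from __future__ import annotations

import io
import logging
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Iterator, Sequence

import numpy as np

from .errors import ParseError, ValidationError

logger = logging.getLogger(__name__)

#: Case-insensitive tokens that mark a missing log2 value.
MISSING_TOKENS = frozenset({"", "na", "nan"})

_CHROM_RE = re.compile(r"^(chr)?(.+)$", re.IGNORECASE)
_SEX_RANK = {"X": 23, "Y": 24, "M": 25, "MT": 25}


def chrom_sort_key(chrom: str) -> tuple:
    """Natural ordering key for chromosome labels.

    chr1 < chr2 < chr10 < chrX < chrY < chrM < anything else (lexical).
    Labels themselves are never rewritten; this key is used only to make
    parsing permutation-invariant.
    """
    body = _CHROM_RE.match(chrom).group(2)
    if body.isdigit():
        return (0, int(body), chrom)
    rank = _SEX_RANK.get(body.upper())
    if rank is not None:
        return (0, rank, chrom)
    return (1, 0, chrom)


def normalize_chrom(chrom: str) -> str:
    """Return the label with a leading ``chr`` prefix (``1`` -> ``chr1``).

    Offered as an explicit helper; parsers keep labels verbatim so that
    mismatches against annotation tables stay visible.
    """
    if chrom.lower().startswith("chr"):
        return chrom
    return "chr" + chrom


@dataclass(frozen=True)
class ProbeRecord:
    """One array probe: identifier, name and its genomic interval."""

    probe_id: str
    probe_name: str
    chrom: str
    start: int  # 1-based inclusive bp
    end: int    # 1-based inclusive bp

    def __post_init__(self):
        if not self.chrom:
            raise ValidationError(f"probe {self.probe_id!r}: empty chromosome label")
        if self.start < 1:
            raise ValidationError(f"probe {self.probe_id!r}: start {self.start} < 1")
        if self.end < self.start:
            raise ValidationError(
                f"probe {self.probe_id!r}: end {self.end} < start {self.start}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class AcghDataset:
    """An ordered probe list plus an (n_probes x n_samples) log2-ratio matrix.

    Missing measurements are stored as NaN.  ``gene_map`` optionally maps
    probe_id to a gene symbol for reporting.
    """

    probes: list[ProbeRecord]
    sample_names: list[str]
    values: np.ndarray
    gene_map: dict[str, str] | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape != (len(self.probes), len(self.sample_names)):
            raise ValidationError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.probes)} probes x {len(self.sample_names)} samples"
            )
        if len(set(self.sample_names)) != len(self.sample_names):
            raise ValidationError("sample names are not unique")
        self._canonicalize()

    def _canonicalize(self) -> None:
        order = sorted(
            range(len(self.probes)),
            key=lambda i: (
                chrom_sort_key(self.probes[i].chrom),
                self.probes[i].start,
                self.probes[i].end,
                self.probes[i].probe_id,
            ),
        )
        self.probes = [self.probes[i] for i in order]
        if len(order):
            self.values = self.values[order, :]

    @property
    def n_probes(self) -> int:
        return len(self.probes)

    @property
    def n_samples(self) -> int:
        return len(self.sample_names)

    def chromosomes(self) -> list[str]:
        """Unique chromosome labels in canonical order."""
        seen: dict[str, None] = {}
        for p in self.probes:
            seen.setdefault(p.chrom, None)
        return list(seen)

    def chrom_rows(self, chrom: str) -> np.ndarray:
        """Row indices of the probes on ``chrom`` (canonical order)."""
        return np.array([i for i, p in enumerate(self.probes) if p.chrom == chrom], dtype=int)

    def sample_index(self, sample: str) -> int:
        try:
            return self.sample_names.index(sample)
        except ValueError:
            raise ValidationError(f"unknown sample {sample!r}") from None


def _open(source, mode: str = "r") -> tuple[IO[str], bool]:
    if isinstance(source, (str, Path)):
        return open(source, mode, encoding="utf-8", newline=""), True
    return source, False


def _is_number(token: str) -> bool:
    try:
        float(token)
        return True
    except ValueError:
        return False


def parse_acgh(source, header_policy: str = "auto") -> AcghDataset:
    """Parse the tab-delimited aCGH table into a canonical :class:`AcghDataset`.

    Parameters
    ----------
    source : path or text stream
    header_policy : {"auto", "header", "none"}
        "auto" treats the first line as a header when its 4th field is not
        numeric; "header"/"none" force the interpretation.  Without a header
        samples are named ``sample_1`` ... ``sample_k``.
    """
    if header_policy not in ("auto", "header", "none"):
        raise ValidationError(f"unknown header_policy {header_policy!r}")
    stream, should_close = _open(source)
    try:
        lines = stream.read().splitlines()
    finally:
        if should_close:
            stream.close()

    rows: list[tuple[int, list[str]]] = []
    for lineno, raw in enumerate(lines, start=1):
        if raw.strip() == "":
            continue
        rows.append((lineno, raw.split("\t")))
    if not rows:
        raise ParseError("empty aCGH file")

    first_lineno, first = rows[0]
    if len(first) < 6:
        raise ParseError(
            f"expected >= 6 tab-delimited columns, found {len(first)}", line=first_lineno
        )
    has_header = header_policy == "header" or (
        header_policy == "auto" and not _is_number(first[3])
    )
    if has_header:
        sample_names = [c.strip() for c in first[5:]]
        data_rows = rows[1:]
        if not data_rows:
            raise ParseError("aCGH file contains a header but no data rows")
    else:
        sample_names = [f"sample_{i + 1}" for i in range(len(first) - 5)]
        data_rows = rows

    n_cols = len(first)
    probes: list[ProbeRecord] = []
    values: list[list[float]] = []
    for lineno, fields in data_rows:
        if len(fields) != n_cols:
            raise ParseError(
                f"ragged row: {len(fields)} columns, expected {n_cols}", line=lineno
            )
        probe_id, probe_name, chrom = fields[0], fields[1], fields[2]
        try:
            start, end = int(fields[3]), int(fields[4])
        except ValueError:
            raise ParseError(
                f"non-integer coordinate {fields[3]!r}/{fields[4]!r}", line=lineno
            ) from None
        try:
            probes.append(ProbeRecord(probe_id, probe_name, chrom, start, end))
        except ValidationError as exc:
            raise ValidationError(f"line {lineno}: {exc}") from None
        row_vals = []
        for tok in fields[5:]:
            t = tok.strip()
            if t.lower() in MISSING_TOKENS:
                row_vals.append(math.nan)
            elif _is_number(t):
                row_vals.append(float(t))
            else:
                raise ParseError(f"non-numeric log2 value {tok!r}", line=lineno)
        values.append(row_vals)

    return AcghDataset(probes, sample_names, np.array(values, dtype=float))


def write_acgh(dataset: AcghDataset, dest, header: bool = True) -> None:
    """Write a dataset back to the aCGH text format (full float precision)."""
    stream, should_close = _open(dest, "w")
    try:
        if header:
            stream.write("\t".join(["probe_id", "probe_name", "chrom", "start", "end"]
                                   + list(dataset.sample_names)) + "\n")
        for i, p in enumerate(dataset.probes):
            vals = [
                "NA" if math.isnan(v) else format(v, ".12g") for v in dataset.values[i]
            ]
            stream.write(
                "\t".join([p.probe_id, p.probe_name, p.chrom, str(p.start), str(p.end)] + vals)
                + "\n"
            )
    finally:
        if should_close:
            stream.close()


def parse_gene_map(source) -> dict[str, str]:
    """Parse the two-column probe_id -> gene TSV.

    A duplicated probe_id keeps the last occurrence and logs a warning.
    """
    stream, should_close = _open(source)
    try:
        mapping: dict[str, str] = {}
        for lineno, raw in enumerate(stream.read().splitlines(), start=1):
            if raw.strip() == "":
                continue
            fields = raw.split("\t")
            if len(fields) != 2:
                raise ParseError(
                    f"expected 2 columns in gene map, found {len(fields)}", line=lineno
                )
            probe_id, gene = fields[0].strip(), fields[1].strip()
            if probe_id in mapping:
                logger.warning(
                    "gene map line %d: duplicate probe_id %r (keeping last)", lineno, probe_id
                )
            mapping[probe_id] = gene
        return mapping
    finally:
        if should_close:
            stream.close()


SEGMENT_COLUMNS = (
    "chrom", "start", "end", "sample", "type", "n_probes",
    "sw_score", "segmental_mean", "qc_flags", "known_status",
)


def write_segments(segments: Sequence, dest) -> None:
    """Write detected segments as the canonical TSV (1-based inclusive, 6 sig digits).

    Rows are sorted by (chrom, start, sample); ``qc_flags`` is a comma-joined
    sorted list or ``.``; ``known_status`` is ``.`` when unset.
    """
    ordered = sorted(segments, key=lambda s: (chrom_sort_key(s.chrom), s.start, s.sample))
    stream, should_close = _open(dest, "w")
    try:
        stream.write("\t".join(SEGMENT_COLUMNS) + "\n")
        for s in ordered:
            flags = ",".join(sorted(s.qc_flags)) if s.qc_flags else "."
            status = s.known_status if s.known_status else "."
            stream.write("\t".join([
                s.chrom, str(s.start), str(s.end), s.sample, s.type, str(s.n_probes),
                format(s.sw_score, ".6g"), format(s.segmental_mean, ".6g"), flags, status,
            ]) + "\n")
    finally:
        if should_close:
            stream.close()


def parse_segments(source) -> list:
    """Re-read a segment TSV written by :func:`write_segments`.

    Probe indices are not stored in the file, so they come back ``None``.
    """
    from .cnv_detect import CnvSegment  # local import to avoid a cycle

    stream, should_close = _open(source)
    try:
        lines = stream.read().splitlines()
    finally:
        if should_close:
            stream.close()
    if not lines:
        raise ParseError("empty segment file")
    header = lines[0].split("\t")
    if tuple(header) != SEGMENT_COLUMNS:
        raise ParseError(f"unexpected segment header {header!r}", line=1)
    out = []
    for lineno, raw in enumerate(lines[1:], start=2):
        if raw.strip() == "":
            continue
        f = raw.split("\t")
        if len(f) != len(SEGMENT_COLUMNS):
            raise ParseError(f"expected {len(SEGMENT_COLUMNS)} columns, found {len(f)}",
                             line=lineno)
        try:
            out.append(CnvSegment(
                sample=f[3], chrom=f[0], start=int(f[1]), end=int(f[2]),
                first_probe_index=None, last_probe_index=None, type=f[4],
                sw_score=float(f[6]), segmental_mean=float(f[7]), n_probes=int(f[5]),
                qc_flags=set() if f[8] == "." else set(f[8].split(",")),
                known_status=None if f[9] == "." else f[9],
            ))
        except ValueError as exc:
            raise ParseError(str(exc), line=lineno) from None
    return out
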