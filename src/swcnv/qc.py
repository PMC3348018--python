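"""Programmatic spurious-signal QC for detected copy-number segments.

Array CNV calls are notorious for false positives driven by platform noise;
the classic workflow separates spurious from true signals by eyeballing the
log2 values inside each call.  This module formalizes that inspection as
three reproducible rules on the region statistics — too few probes, a
segmental mean too close to zero, and excessive within-region variance —
plus the user-defined high/low outlier filter applied before the variance
check.  Flags annotate segments; nothing is deleted, so the audit trail of
what was excluded and why survives into the output.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .acgh_io import AcghDataset
from .cnv_detect import CnvSegment
from .errors import ValidationError

FLAG_SHORT = "short"
FLAG_WEAK = "weak"
FLAG_NOISY = "noisy"
FLAG_PASS = "pass"


@dataclass(frozen=True)
class RegionSummary:
    """The six regional statistics plus counts.

    ``variance`` is the sample variance (n-1 denominator) and is ``None``
    when only one value is available.
    """

    mean: float
    median: float
    max: float
    min: float
    sum: float
    variance: float | None
    n: int
    n_missing: int


@dataclass(frozen=True)
class QcCriteria:
    """Thresholds for the spurious-signal flags.

    Defaults (5 probes, |segmental mean| >= 0.3 log2 units, region variance
    <= 0.25) are deliberately visible, ordinary choices for noisy array data;
    every one is expected to be tuned per platform.
    """

    min_probes: int = 5
    min_abs_segmental_mean: float = 0.3
    max_region_variance: float = 0.25
    outlier_low: float | None = None
    outlier_high: float | None = None

    def __post_init__(self):
        if (self.outlier_low is not None and self.outlier_high is not None
                and not self.outlier_low < self.outlier_high):
            raise ValidationError("outlier_low must be < outlier_high")


def region_summary(values: Sequence[float]) -> RegionSummary:
    """Mean, median, max, min, sum and sample variance of a region's log2 values.

    NaNs count as missing and are excluded; an all-missing region is an error.
    """
    x = np.asarray(values, dtype=float)
    finite = x[~np.isnan(x)]
    n_missing = int(x.size - finite.size)
    if finite.size == 0:
        raise ValidationError("region_summary of all-missing values")
    return RegionSummary(
        mean=float(np.mean(finite)),
        median=float(np.median(finite)),
        max=float(np.max(finite)),
        min=float(np.min(finite)),
        sum=float(np.sum(finite)),
        variance=float(np.var(finite, ddof=1)) if finite.size > 1 else None,
        n=int(finite.size),
        n_missing=n_missing,
    )


def outlier_filter(
    values: Sequence[float], low: float, high: float
) -> tuple[np.ndarray, int]:
    """Keep values with ``low <= x <= high``; return (kept, n_removed).

    NaNs are removed.  Idempotent: filtering the output again changes nothing.
    """
    if not low < high:
        raise ValidationError(f"outlier bounds require low < high, got {low} >= {high}")
    x = np.asarray(values, dtype=float)
    keep = (x >= low) & (x <= high)
    return x[keep], int(x.size - keep.sum())


def qc_flag_segments(
    segments: Iterable[CnvSegment],
    dataset: AcghDataset,
    criteria: QcCriteria = QcCriteria(),
) -> list[CnvSegment]:
    """Populate ``qc_flags`` on each segment; segments are never dropped.

    Flags: ``short`` when the segment spans fewer than ``min_probes`` probes;
    ``weak`` when |segmental_mean| is below ``min_abs_segmental_mean``;
    ``noisy`` when the sample variance of the region's log2 values (after the
    optional outlier filter) exceeds ``max_region_variance``; ``pass`` when
    none fire.  Filtering to passing segments only is an export decision,
    made elsewhere.
    """
    segments = list(segments)
    for seg in segments:
        flags: set[str] = set()
        if seg.n_probes < criteria.min_probes:
            flags.add(FLAG_SHORT)
        if abs(seg.segmental_mean) < criteria.min_abs_segmental_mean:
            flags.add(FLAG_WEAK)
        flags |= _noise_flag(seg, dataset, criteria)
        seg.qc_flags = flags if flags else {FLAG_PASS}
    return segments


def _noise_flag(seg: CnvSegment, dataset: AcghDataset, criteria: QcCriteria) -> set[str]:
    values = region_values(seg, dataset)
    if criteria.outlier_low is not None and criteria.outlier_high is not None:
        values, _ = outlier_filter(values, criteria.outlier_low, criteria.outlier_high)
    values = values[~np.isnan(values)]
    if values.size > 1:
        if float(np.var(values, ddof=1)) > criteria.max_region_variance:
            return {FLAG_NOISY}
    return set()


def region_values(seg: CnvSegment, dataset: AcghDataset) -> np.ndarray:
    """The segment's per-probe log2 values (may include NaN for missing probes).

    Raises ``ValidationError`` naming the segment when it cannot be resolved
    against the dataset (unknown sample/chromosome or missing probe indices).
    """
    label = f"{seg.sample}:{seg.chrom}:{seg.start}-{seg.end}"
    if seg.first_probe_index is None or seg.last_probe_index is None:
        raise ValidationError(f"segment {label} carries no probe indices")
    try:
        col = dataset.sample_index(seg.sample)
    except ValidationError:
        raise ValidationError(f"segment {label}: sample not in dataset") from None
    rows = dataset.chrom_rows(seg.chrom)
    if rows.size == 0:
        raise ValidationError(f"segment {label}: chromosome not in dataset")
    if not (0 <= seg.first_probe_index <= seg.last_probe_index < rows.size):
        raise ValidationError(f"segment {label}: probe indices out of range")
    return dataset.values[rows[seg.first_probe_index:seg.last_probe_index + 1], col]
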