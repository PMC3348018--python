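"""Smith-Waterman island segmentation of log2-ratio profiles.

The detector reduces local alignment to one dimension: probe log2 ratios are
converted to threshold-subtracted scores and the running score
``S_i = max(0, S_{i-1} + s_i)`` is tracked along each chromosome.  Maximal
runs with ``S_i > 0`` are candidate copy-number islands; an island is reported
from the run's first probe to the first probe attaining the run's maximum
``S``, with that maximum as its score.  The threshold is set robustly per
sample and chromosome at ``median +/- k * MAD`` of the log2 values, and
islands spanning fewer than ``L`` probes are discarded — raising either knob
makes detection strictly more conservative.

Gains and losses are two symmetric passes: the gain pass scores
``x_i - (median + k*MAD)``, the loss pass ``(median - k*MAD) - x_i``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .acgh_io import AcghDataset, chrom_sort_key
from .errors import DegenerateDispersionError, ValidationError

GAIN = "gain"
LOSS = "loss"
BOTH = "both"
NEUTRAL = "neutral"
CONFLICT = "conflict"


@dataclass(frozen=True)
class CnvParams:
    """Detection knobs.

    mad_multiplier
        k in the ``median +/- k*MAD`` threshold (dimensionless, > 0).
    min_island_probes
        minimum island span L, counted in probes (>= 1).
    direction
        "gain", "loss" or "both".
    abs_threshold
        optional absolute half-width (log2 units) replacing ``k*MAD`` when the
        MAD is zero (constant signal); without it a zero MAD is an error.
    """

    mad_multiplier: float = 3.0
    min_island_probes: int = 5
    direction: str = BOTH
    abs_threshold: float | None = None

    def __post_init__(self):
        if self.mad_multiplier <= 0:
            raise ValidationError("mad_multiplier must be > 0")
        if self.min_island_probes < 1:
            raise ValidationError("min_island_probes must be >= 1")
        if self.direction not in (GAIN, LOSS, BOTH):
            raise ValidationError(f"direction must be gain/loss/both, got {self.direction!r}")


@dataclass
class CnvSegment:
    """A detected gain or loss island.

    ``first_probe_index``/``last_probe_index`` index the chromosome's probe
    order (0-based); ``n_probes`` is that inclusive span, so probes whose
    value is missing but which sit inside the island are counted.
    ``sw_score`` is the sum of threshold-subtracted scores over the island,
    i.e. the running-score maximum that defined it.
    """

    sample: str
    chrom: str
    start: int  # bp, 1-based inclusive: first probe's start
    end: int    # bp, 1-based inclusive: last probe's end
    first_probe_index: int | None
    last_probe_index: int | None
    type: str
    sw_score: float
    segmental_mean: float
    n_probes: int
    qc_flags: set[str] = field(default_factory=set)
    known_status: str | None = None

    def __post_init__(self):
        if self.start > self.end:
            raise ValidationError(f"segment start {self.start} > end {self.end}")
        if self.n_probes < 1:
            raise ValidationError("segment must span >= 1 probe")
        if self.type not in (GAIN, LOSS):
            raise ValidationError(f"segment type must be gain or loss, got {self.type!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def mad(values: Sequence[float]) -> float:
    """Unscaled median absolute deviation, ``median(|x - median(x)|)``.

    No 1.4826 Gaussian consistency factor is applied; the detection threshold
    absorbs any scale through its multiplier.
    """
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValidationError("mad of empty sequence")
    if np.isnan(x).any():
        raise ValidationError("mad input contains NaN; remove missing values first")
    return float(np.median(np.abs(x - np.median(x))))


def sw_islands(scores: Sequence[float]) -> list[tuple[int, int, float]]:
    """Positive-scoring islands of the 1-D Smith-Waterman recurrence.

    Returns ``(start_index, end_index, score)`` triples, left to right.  Each
    maximal run of indices with running score ``S_i > 0`` yields exactly one
    island, ending at the run's first argmax of ``S`` (leftmost tie-break);
    its score is that maximum, which equals the plain sum of ``scores`` over
    the island.
    """
    islands: list[tuple[int, int, float]] = []
    s = 0.0
    run_start = None
    run_max = 0.0
    run_argmax = -1
    for i, sc in enumerate(scores):
        s = s + float(sc)
        if s < 0.0:
            s = 0.0
        if s > 0.0:
            if run_start is None:
                run_start, run_max, run_argmax = i, s, i
            elif s > run_max:
                run_max, run_argmax = s, i
        elif run_start is not None:
            islands.append((run_start, run_argmax, run_max))
            run_start = None
    if run_start is not None:
        islands.append((run_start, run_argmax, run_max))
    return islands


def detect_cnv(
    dataset: AcghDataset, sample: str, chrom: str, params: CnvParams
) -> list[CnvSegment]:
    """Detect gain/loss segments for one sample on one chromosome.

    Missing probe values are excised before the recurrence (gaps do not break
    islands); islands are mapped back to genomic coordinates through the
    surviving probes.  Requires at least two non-missing probes.

    Raises
    ------
    DegenerateDispersionError
        when MAD = 0 and ``params.abs_threshold`` is not set.
    """
    col = dataset.sample_index(sample)
    rows = dataset.chrom_rows(chrom)
    if rows.size == 0:
        raise ValidationError(f"chromosome {chrom!r} not present in dataset")
    vals = dataset.values[rows, col]
    keep = ~np.isnan(vals)
    x = vals[keep]
    kept_rel = np.nonzero(keep)[0]  # chromosome probe order indices
    if x.size < 2:
        raise ValidationError(
            f"need >= 2 non-missing probes on {chrom} for {sample}, found {x.size}"
        )
    m = float(np.median(x))
    d = mad(x)
    if d == 0.0:
        if params.abs_threshold is None:
            raise DegenerateDispersionError(
                f"degenerate dispersion: MAD = 0 on {chrom} for {sample} "
                "(set abs_threshold to proceed)"
            )
        half_width = params.abs_threshold
    else:
        half_width = params.mad_multiplier * d

    passes = []
    if params.direction in (GAIN, BOTH):
        passes.append((GAIN, x - (m + half_width)))
    if params.direction in (LOSS, BOTH):
        passes.append((LOSS, (m - half_width) - x))

    chrom_probes = [dataset.probes[r] for r in rows]
    segments: list[CnvSegment] = []
    for seg_type, scores in passes:
        for a, b, score in sw_islands(scores):
            first = int(kept_rel[a])
            last = int(kept_rel[b])
            n = last - first + 1
            if n < params.min_island_probes:
                continue
            segments.append(CnvSegment(
                sample=sample,
                chrom=chrom,
                start=chrom_probes[first].start,
                end=chrom_probes[last].end,
                first_probe_index=first,
                last_probe_index=last,
                type=seg_type,
                sw_score=float(score),
                segmental_mean=float(np.mean(x[a:b + 1])),
                n_probes=n,
            ))
    segments.sort(key=lambda s: (s.start, s.end, s.type))
    return segments


@dataclass
class DetectResult:
    """All segments from a whole-dataset run plus non-fatal issues.

    ``segments`` maps (sample, chrom) to the segment list; ``issues`` records
    per-(sample, chrom) degenerate-dispersion (or too-few-probe) conditions
    that were skipped rather than raised.
    """

    segments: dict[tuple[str, str], list[CnvSegment]]
    issues: list[tuple[str, str, str]]

    def all_segments(self) -> list[CnvSegment]:
        out: list[CnvSegment] = []
        for segs in self.segments.values():
            out.extend(segs)
        return out


def detect_all(dataset: AcghDataset, params: CnvParams) -> DetectResult:
    """Run :func:`detect_cnv` over every sample x chromosome, collecting issues."""
    result: dict[tuple[str, str], list[CnvSegment]] = {}
    issues: list[tuple[str, str, str]] = []
    for sample in dataset.sample_names:
        for chrom in dataset.chromosomes():
            try:
                result[(sample, chrom)] = detect_cnv(dataset, sample, chrom, params)
            except (DegenerateDispersionError, ValidationError) as exc:
                result[(sample, chrom)] = []
                issues.append((sample, chrom, str(exc)))
    return DetectResult(result, issues)


def segment_matrix(
    segments_by_sample: Mapping[str, Iterable[CnvSegment]],
    chrom: str,
    bin_size: int,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Rasterize per-sample segments onto fixed genomic bins.

    A bin takes the value ``gain`` (``loss``) for a sample when that sample's
    gain (loss) segments cover at least half of the bin; when both directions
    independently reach half coverage the bin is ``conflict``; otherwise
    ``neutral``.  This is the matrix underlying a cross-sample heat-map view.

    Returns
    -------
    matrix : DataFrame, samples x bins, values in {gain, loss, neutral, conflict}
    bins : DataFrame with columns bin, start, end (1-based inclusive)
    """
    if bin_size < 1:
        raise ValidationError("bin_size must be >= 1")
    max_end = 0
    for segs in segments_by_sample.values():
        for s in segs:
            if s.chrom == chrom:
                max_end = max(max_end, s.end)
    n_bins = max(1, -(-max_end // bin_size)) if max_end else 0
    bin_starts = np.arange(n_bins) * bin_size + 1
    bins = pd.DataFrame({
        "bin": np.arange(n_bins),
        "start": bin_starts,
        "end": bin_starts + bin_size - 1,
    })

    samples = list(segments_by_sample)
    matrix = np.full((len(samples), n_bins), NEUTRAL, dtype=object)
    for si, sample in enumerate(samples):
        cov = {GAIN: np.zeros(n_bins), LOSS: np.zeros(n_bins)}
        for s in segments_by_sample[sample]:
            if s.chrom != chrom:
                continue
            lo, hi = s.start - 1, s.end  # half-open
            first_bin, last_bin = lo // bin_size, (hi - 1) // bin_size
            for b in range(first_bin, last_bin + 1):
                b_lo, b_hi = b * bin_size, (b + 1) * bin_size
                cov[s.type][b] += max(0, min(hi, b_hi) - max(lo, b_lo))
        half = bin_size / 2.0
        gain_hit = cov[GAIN] >= half
        loss_hit = cov[LOSS] >= half
        matrix[si, gain_hit & ~loss_hit] = GAIN
        matrix[si, loss_hit & ~gain_hit] = LOSS
        matrix[si, gain_hit & loss_hit] = CONFLICT
    return pd.DataFrame(matrix, index=samples, columns=bins["bin"]), bins
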