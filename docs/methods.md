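# Methods

This note records the model, the parameters that matter, the numerical
conventions, and the limits of what the synthetic test-bed demonstrates.
It states no result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Segmentation model

The detector treats CNV calling on a log2-ratio profile as a maximal-scoring
-segment problem, the one-dimensional reduction of Smith-Waterman local
alignment. Per sample and per chromosome:

1. Robust centre and scale: `m = median(x)`, `d = MAD(x) = median(|x − m|)`,
   deliberately **unscaled** (no 1.4826 Gaussian consistency factor) — the
   user-facing multiplier `k` absorbs scale, so applying the factor would
   only relabel `k`.
2. Threshold-subtracted scores, one pass per direction:
   gains `s_i = x_i − (m + k·d)`, losses `s_i = (m − k·d) − x_i`.
3. Recurrence `S_i = max(0, S_{i−1} + s_i)`. A maximal run of probes with
   `S_i > 0` yields exactly one island, from the run's first probe to the
   *first* index attaining the run's maximum `S` (leftmost tie-break, for
   determinism); the maximum equals the island's plain score sum. Runs are
   not re-mined recursively after the argmax — a deliberate simplification,
   see limitations.
4. Islands spanning fewer than `L` probes are discarded; survivors become
   segments carrying coordinates (first probe's start to last probe's end,
   1-based inclusive), the SW score, probe count, and the segmental mean of
   the probes' log2 values.

The threshold is computed **per chromosome and per sample**, so a
chromosome-scale shift does not poison the genome-wide scale. (A
whole-genome threshold would be a one-line variant; per-chromosome is the
default and what the tests exercise.)

`MAD = 0` (constant or near-constant signal) makes the threshold collapse
onto the median and would call every fluctuation; it is an error by default,
with an explicit `abs_threshold` (absolute half-width in log2 units)
available to proceed deliberately. In whole-dataset runs
(`detect_all`) these conditions are collected as per-(sample, chromosome)
issues rather than raised.

Missing probe values (empty/NA/NaN fields) are excised before the
recurrence — gaps neither score nor break islands — and islands are mapped
back to genomic coordinates through the surviving probes. Probe indices and
`n_probes` refer to the chromosome's full probe order, so a missing probe
inside an island is counted in its span.

### Parameters

| parameter | meaning | default | rationale |
|---|---|---|---|
| `mad_multiplier` (k) | threshold half-width in MADs | 3.0 | ≈2σ for Gaussian noise; the conventional "stringent but sensitive" setting the test-bed is calibrated around |
| `min_island_probes` (L) | minimum island span, probes | 5 | suppresses single-probe noise islands at typical array densities |
| `direction` | gain / loss / both | both | symmetric passes |
| `abs_threshold` | fallback half-width, log2 | none | zero-MAD escape hatch, opt-in |

The block length is measured in **probes**, not bp: the dynamic program
runs on the probe sequence, and a bp criterion would vary with platform
spacing. Strictness is monotone in both knobs at these scales (verified on
50 seeded datasets in the acceptance suite).

## QC rules

Visual triage of calls is replaced by three explicit flags —
`short` (`n_probes < min_probes`, default 5), `weak`
(`|segmental_mean| < 0.3` log2 by default, about half the displacement of a
single-copy change), `noisy` (region sample variance > 0.25 by default,
computed after the optional user-defined low/high outlier filter) — plus
`pass` when none fire. Variance uses the n−1 denominator and is undefined
(never flagged) for single-probe regions. Flags always annotate and never
delete; dropping failed segments is an explicit export option. The defaults
are visible, ordinary choices for noisy array data, not fitted quantities;
the rules themselves are this package's formalization of a manual practice,
so real-data thresholds should be tuned per platform.

## Annotation

Catalogue comparison uses an interval tree per chromosome; a segment is
`known` when some record overlaps it by ≥ 1 bp with reciprocal overlap
`min(ov/|segment|, ov/|record|) ≥ min_reciprocal` (default 0, i.e. any
overlap — stricter reciprocal matching is an explicit choice). Chromosome
labels are compared verbatim and case-sensitively; a `normalize_chrom`
helper exists, but silent normalization is avoided so label mismatches
against a catalogue surface as all-novel rather than as wrong verdicts.
Variation types do not constrain matching by default (a gain may be known
via a "loss" record); `match_type` enforces compatibility, mapping common
spellings (duplication/insertion → gain, deletion → loss) and treating
unspecific types ("CNV", "complex") as compatible with both.

## Alignment analyses

The pileup walks each read's CIGAR once: M/=/X ops contribute the read base
(below-`min_baseq` bases are skipped, not the whole read), D ops contribute
`DEL`, N ops and insertions contribute nothing; a read adds at most one
count per column, and depth is identically the sum of the six counters.
Unmapped, secondary, duplicate and QC-fail records are excluded by default
and every filter is adjustable; mapq/baseq floors default to 0 so raw
counts are reproducible.

The SNP caller is a pure frequency-threshold rule (defaults: depth ≥ 5,
alt fraction ≥ 0.2, most frequent non-reference substitution, ties by count
then alphabet) — not a genotype-likelihood model. That is sufficient for
inspecting planted or high-confidence variants and for cross-sample
comparison, and is documented as such; it has no notion of base-quality
weighting, strand bias or mapping artefacts.

The deletion scan operates on **base coverage** (`depth − DEL`): a read
spanning a deletion with a D op marks the locus as covered-by-evidence but
contributes no sequence there, and it is the absence of aligned bases that
signals a homozygous deletion. Runs of base coverage ≤ floor (default 0)
spanning ≥ `min_span` bp are reported with their mean base coverage.

Between-sample comparison treats a site as differing when called in exactly
one sample or with different alternate alleles in both; "consecutive"
differing sites are adjacent entries of the merged position-sorted site
list (any shared identical call breaks a run; runs never cross
chromosomes). A bp-distance cap is deliberately not imposed — site order is
the minimal reading of consecutiveness on sparse call sets.

## Synthetic data: what it emulates, what it does not

The aCGH generator produces evenly spaced probes (1 kb spacing, 60 bp
probes by default), a flat baseline, planted events as additive log2 deltas
over probe spans, and i.i.d. Gaussian probe noise (sd 0.15 log2 units by
default — the scale the detection defaults are calibrated against). It does
**not** model autocorrelated "waves", GC bias, outlier probes, or
platform-specific missingness; passing recovery tests therefore shows
correctness of the algorithmic chain under the model's own noise
assumptions, not robustness to real-array artefacts.

The read simulator samples fixed-length single-end reads uniformly from a
donor genome — the reference with the planted deletion excised — so
junction-spanning reads genuinely carry D CIGAR ops and the deleted
interval receives no bases at all; planted SNPs appear per covering read
with probability equal to their allele fraction, plus an optional uniform
substitution error rate. No paired ends, no indel errors, no quality-score
ladder. The number of reads is chosen so interior coverage equals the
requested mean depth (edge positions run slightly lower).

Generators are pure functions of their spec, seed included; identical specs
give byte-identical files.

## Problem sizes in the acceptance run

The acceptance script regenerates everything at the sizes its checks are
stated for: 1000 random score vectors (length ≤ 200) for the segmentation
oracle, 50 seeded datasets (200 probes, one gain + one loss) for
monotonicity, 100 seeds each for recovery (10-probe +1.0 event in sd-0.15
noise, k = 3, L = 5) and event-free specificity, 500 random segment/record
sets (≤ 100 intervals each) for the annotation oracle, 100 random SAMs
(≤ 50 reads, 500 bp reference, random mapq/baseq floors) for the pileup
oracle, 20 seeds of a 500 bp deletion at 30× on a 10 kb contig for the
deletion scan, and a 250-probe × 3-sample dataset for round-trip checks.
The whole run takes a few seconds on one CPU.

## Numerical conventions and degenerate inputs

* Files are 1-based inclusive throughout; all internal interval arithmetic
  is 0-based half-open, converted only at the I/O boundary.
* Parsed datasets are canonicalized (probes sorted by start, end, probe id
  within chromosomes; chromosomes in natural order: chr2 < chr10 < chrX),
  so row-permuted inputs are indistinguishable after parsing.
* aCGH tables are written at 12 significant digits (round-trip error below
  1e-9); segment TSVs at 6 significant digits, making re-write a byte-level
  fixed point at the printed precision.
* The bin matrix (`segment_matrix`) assigns a bin to gain/loss when
  segments of that type cover ≥ 50% of the bin; if both directions reach
  50% independently the bin is `conflict`. Bins are a fixed width grid from
  position 1; same-type overlapping segments are not double-counted against
  the threshold in any detection output (one pass yields disjoint islands).
* Ties everywhere break deterministically (leftmost argmax; alt alleles by
  count then alphabet; hits by overlap then id).

## Known limitations

* One island per positive run: a run containing two well-separated maxima
  yields only the leftmost island. A corollary is that segment *count* is
  not perfectly monotone in `k` at very small `L` (a stricter threshold can
  split one noisy run into two surviving islands); at the documented
  defaults (L = 5) no violation occurs across the acceptance sweep.
* No CBS/HMM alternatives, no wave/GC correction, no multi-threshold
  robustness sweep: the detector exposes exactly one threshold family.
* The SNP caller is not a genotyper; the deletion scan finds homozygous
  losses only (heterozygous losses halve, not zero, the coverage).
* Annotation operates on local catalogue snapshots in the package's own
  TSV fixture format, not on any live database dialect.
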