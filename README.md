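# swcnv

Copy-number variant (CNV) detection and triage from array-CGH log2-ratio
profiles and sequence alignments — as a Python library with a thin command
line on top.

Array CGH measures, probe by probe, the log2 ratio of sample to reference
DNA abundance: ~0 where copy number is normal, shifted up over duplicated
segments and down over deletions. CNV callers on such data are plagued by
false positives from platform noise, so a practical workflow needs four
things beyond the segmentation itself: reproducible quality control on every
call, a verdict on whether a call was previously reported, cross-sample
comparison, and — for sequencing data — per-locus read depth and allele
frequencies to inspect candidate regions. `swcnv` implements that whole
loop headlessly, for pipeline use rather than point-and-click inspection.

## The method

**Segmentation.** For a sample's log2 values `x_1..x_n` along one chromosome,
compute the median `m` and the (unscaled) median absolute deviation
`MAD = median(|x_i - median(x)|)`, and form threshold-subtracted scores

    gain pass:  s_i = x_i - (m + k·MAD)
    loss pass:  s_i = (m - k·MAD) - x_i

Then run the one-dimensional Smith-Waterman recurrence
`S_i = max(0, S_{i-1} + s_i)` with `S_0 = 0`. Each maximal run of probes
with `S_i > 0` is a candidate *island*; it is reported from the run's first
probe to the first probe attaining the run's maximum `S` (which equals the
island's score, the maximum contiguous sum of `s_i`). Islands spanning fewer
than `L` probes are dropped. Raising `k` or `L` makes detection stricter.
Each surviving island becomes a gain or loss segment with its *segmental
mean* — the average log2 ratio inside the call, the single most informative
number for judging whether the call is real.

**QC.** Three explicit rules replace manual visual inspection: `short`
(fewer than a minimum number of probes), `weak` (|segmental mean| below a
floor), `noisy` (within-region sample variance above a cap, computed after
an optional user-defined high/low outlier filter). Flags annotate segments;
nothing is silently deleted.

**Annotation.** A segment is `known` if at least one record of a local
DGV-style catalogue on the same chromosome overlaps it with reciprocal
overlap `min(ov/|segment|, ov/|record|)` at or above a threshold (default 0:
any shared base pair); otherwise `novel`. dbSNP-style records can be listed
per locus range.

**Alignments.** From SAM/BAM, `swcnv` computes per-position pileups
(A/C/G/T/N/deletion counts; depth = their sum), allele frequencies, simple
frequency-threshold SNP calls (most frequent non-reference base with
sufficient depth and allele fraction), low-coverage runs as homozygous-
deletion candidates, and between-sample SNP differences with runs of
consecutive differing sites reported as CNV candidate regions.

A first-class synthetic-data module (`swcnv.synth`) generates all inputs —
aCGH tables with planted CNVs, FASTA+SAM with planted SNPs and deletions,
catalogue tables — with machine-readable ground truth, deterministically
under a seed.

## Worked example

`examples/detect_cnvs.py` plants a 15-probe gain and a 12-probe loss in
Gaussian noise (sd 0.15 log2 units) and detects them at the default
strictness:

```
planted events:
  chr1:40001-54060  delta +1.0
  chr1:120001-131060  delta -1.0

detected segments (k=3, L=5):
  chr1:40001-54060  gain  15 probes  sw_score 10.42  segmental mean +1.02
  chr1:120001-131060  loss  12 probes  sw_score 7.98  segmental mean -1.01
```

Both planted events are recovered exactly; the segmental means sit at the
planted ±1.0 and `sw_score` is the accumulated above-threshold evidence.
`examples/qc_and_annotate.py` continues the loop (QC flags, known/novel
verdicts) and `examples/read_depth_and_snps.py` covers the alignment side —
its planted 500 bp deletion comes back as a zero-coverage run at exactly
`ref1:6001-6500`.

The same capabilities are available from the shell:

```sh
swcnv simulate acgh --spec spec.json --out-prefix sim
swcnv detect --acgh sim.acgh.tsv --mad-k 3 --min-probes 5 --out segs.tsv
swcnv qc --segments segs.tsv --acgh sim.acgh.tsv --out qc.tsv
swcnv annotate --segments qc.tsv --dgv dgv.tsv --out annotated.tsv
swcnv depth --bam sample.sam --region chr1:1-10000 --out depth.tsv
```

Every command writes a `<out>.manifest.json` with the parameters and tool
version; identical inputs, flags and seeds give byte-identical outputs.

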