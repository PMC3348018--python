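"""Synthetic aCGH profiles, sequencing alignments and annotation tables.

Every generator is a pure function of its spec (seed included), so fixtures
are reproducible bit for bit and each comes with a machine-readable truth
table for closing the loop in end-to-end tests:

* :func:`simulate_acgh` — evenly spaced probes whose log2 ratios are a flat
  baseline plus planted gain/loss deltas plus i.i.d. Gaussian noise.  Noise is
  deliberately uncorrelated: the segmentation model assumes independent probe
  noise, and wave/GC artifacts of real arrays are out of scope.
* :func:`simulate_reads` — single-end, fixed-length, error-optional reads
  sampled uniformly from a donor genome (the reference minus an optional
  homozygous deletion), written as coordinate-sorted SAM; reads spanning the
  deletion carry a ``D`` CIGAR op.  Planted SNPs appear in each covering read
  with probability equal to their allele fraction.
* :func:`make_annotation_fixtures` — catalogue tables (DGV-style and
  dbSNP-style) derived from a truth table with optional coordinate jitter and
  decoy records, for exercising known/novel classification.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import pysam

from .acgh_io import AcghDataset, ProbeRecord, write_acgh
from .errors import ValidationError

_BASES = "ACGT"


@dataclass(frozen=True)
class AcghEvent:
    """A planted CNV: a delta added to a probe span of one chromosome.

    ``first_probe``/``last_probe`` are 0-based inclusive indices within the
    chromosome; ``samples`` limits the event to the named samples (None = all).
    """

    chrom: str
    first_probe: int
    last_probe: int
    delta: float
    samples: tuple[str, ...] | None = None


@dataclass(frozen=True)
class AcghSimSpec:
    """Layout and noise model of a synthetic aCGH dataset.

    Defaults describe a modest oligo array: 1 kb probe spacing, 60 bp probes,
    zero baseline and Gaussian probe noise of sd 0.15 log2 units — the noise
    scale against which the documented detection defaults (k = 3, L = 5) are
    calibrated in the test-bed.
    """

    probes_per_chrom: dict[str, int] = field(default_factory=lambda: {"chr1": 200})
    probe_spacing: int = 1000
    probe_length: int = 60
    baseline: float = 0.0
    noise_sd: float = 0.15
    events: tuple[AcghEvent, ...] = ()
    n_samples: int = 1
    seed: int = 0

    def __post_init__(self):
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")
        if self.probe_spacing < 1 or self.probe_length < 1:
            raise ValidationError("probe_spacing and probe_length must be >= 1")
        if self.n_samples < 1:
            raise ValidationError("n_samples must be >= 1")

    @property
    def sample_names(self) -> list[str]:
        return [f"sample_{i + 1}" for i in range(self.n_samples)]


def simulate_acgh(spec: AcghSimSpec) -> tuple[AcghDataset, pd.DataFrame]:
    """Generate the dataset and its truth table.

    Truth columns: sample, chrom, start, end, first_probe, last_probe, delta.
    Overlapping events on the same sample are rejected.
    """
    rng = np.random.default_rng(spec.seed)
    probes: list[ProbeRecord] = []
    chrom_offsets: dict[str, int] = {}
    for chrom, n in spec.probes_per_chrom.items():
        if n < 1:
            raise ValidationError(f"{chrom}: probes_per_chrom must be >= 1")
        chrom_offsets[chrom] = len(probes)
        for i in range(n):
            start = 1 + i * spec.probe_spacing
            probes.append(ProbeRecord(
                probe_id=f"{chrom}_p{i + 1:05d}", probe_name=f"{chrom}_probe_{i + 1}",
                chrom=chrom, start=start, end=start + spec.probe_length - 1,
            ))

    samples = spec.sample_names
    values = np.full((len(probes), spec.n_samples), spec.baseline, dtype=float)

    spans: dict[str, list[tuple[int, int]]] = {s: [] for s in samples}
    truth_rows = []
    for ev in spec.events:
        if ev.chrom not in spec.probes_per_chrom:
            raise ValidationError(f"event on unknown chromosome {ev.chrom!r}")
        n = spec.probes_per_chrom[ev.chrom]
        if not 0 <= ev.first_probe <= ev.last_probe < n:
            raise ValidationError(
                f"event probe span {ev.first_probe}-{ev.last_probe} outside {ev.chrom} "
                f"(n = {n})"
            )
        targets = samples if ev.samples is None else list(ev.samples)
        off = chrom_offsets[ev.chrom]
        for sample in targets:
            if sample not in spans:
                raise ValidationError(f"event targets unknown sample {sample!r}")
            for lo, hi in spans[sample]:
                if ev.first_probe + off <= hi and lo <= ev.last_probe + off:
                    raise ValidationError(
                        f"overlapping planted events on sample {sample!r}"
                    )
            spans[sample].append((ev.first_probe + off, ev.last_probe + off))
            si = samples.index(sample)
            values[off + ev.first_probe: off + ev.last_probe + 1, si] += ev.delta
            truth_rows.append({
                "sample": sample, "chrom": ev.chrom,
                "start": probes[off + ev.first_probe].start,
                "end": probes[off + ev.last_probe].end,
                "first_probe": ev.first_probe, "last_probe": ev.last_probe,
                "delta": ev.delta,
            })

    if spec.noise_sd > 0:
        values += rng.normal(0.0, spec.noise_sd, size=values.shape)

    dataset = AcghDataset(probes, samples, values)
    truth = pd.DataFrame(
        truth_rows,
        columns=["sample", "chrom", "start", "end", "first_probe", "last_probe", "delta"],
    )
    return dataset, truth


def write_acgh_files(spec: AcghSimSpec, out_prefix: str | Path) -> tuple[Path, Path]:
    """Write ``<prefix>.acgh.tsv`` and ``<prefix>.truth.tsv``; returns the paths."""
    dataset, truth = simulate_acgh(spec)
    out_prefix = Path(out_prefix)
    acgh_path = out_prefix.with_name(out_prefix.name + ".acgh.tsv")
    truth_path = out_prefix.with_name(out_prefix.name + ".truth.tsv")
    write_acgh(dataset, acgh_path)
    truth.to_csv(truth_path, sep="\t", index=False)
    return acgh_path, truth_path


@dataclass(frozen=True)
class ReadSimSpec:
    """A single-contig sequencing experiment with planted variants.

    ``snps`` holds (pos, alt, allele_fraction) with 1-based positions on the
    reference; ``deletion`` is a 1-based inclusive interval removed
    homozygously from the donor genome.  Defaults model a small 10 kb contig
    at 30x with 100 bp error-free reads, ample for read-depth and
    allele-fraction behaviour.
    """

    chrom: str = "ref1"
    ref_length: int = 10_000
    base_probs: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    read_length: int = 100
    mean_depth: float = 30.0
    snps: tuple[tuple[int, str, float], ...] = ()
    deletion: tuple[int, int] | None = None
    error_rate: float = 0.0
    sample: str = "sample_1"
    seed: int = 0

    def __post_init__(self):
        if self.ref_length < self.read_length:
            raise ValidationError("ref_length must be >= read_length")
        if not 0.0 <= self.error_rate < 1.0:
            raise ValidationError("error_rate must be in [0, 1)")
        if abs(sum(self.base_probs) - 1.0) > 1e-9:
            raise ValidationError("base_probs must sum to 1")
        if self.deletion is not None:
            ds, de = self.deletion
            if not 1 <= ds <= de <= self.ref_length:
                raise ValidationError("deletion outside reference")
            if de - ds + 1 >= self.ref_length:
                raise ValidationError("deletion covers the whole reference")
        for pos, alt, frac in self.snps:
            if not 1 <= pos <= self.ref_length:
                raise ValidationError(f"SNP position {pos} outside reference")
            if alt not in _BASES:
                raise ValidationError(f"SNP alt {alt!r} is not A/C/G/T")
            if not 0.0 < frac <= 1.0:
                raise ValidationError(f"SNP allele fraction {frac} outside (0, 1]")
            if self.deletion is not None and self.deletion[0] <= pos <= self.deletion[1]:
                raise ValidationError(f"SNP at {pos} lies inside the planted deletion")


@dataclass
class SimulatedRead:
    """One aligned read before SAM serialization."""

    name: str
    ref_start: int  # 0-based
    cigar: list[tuple[int, int]]
    sequence: str


@dataclass
class ReadSimResult:
    reference: str  # full reference sequence
    reads: list[SimulatedRead]
    truth: pd.DataFrame  # columns: kind, chrom, start, end, ref, alt, fraction


def simulate_reads(spec: ReadSimSpec) -> ReadSimResult:
    """Sample reads from the donor genome and map them back to the reference."""
    rng = np.random.default_rng(spec.seed)
    ref = "".join(rng.choice(list(_BASES), size=spec.ref_length, p=spec.base_probs))

    if spec.deletion is not None:
        del_start0, del_end0 = spec.deletion[0] - 1, spec.deletion[1]  # half-open
    else:
        del_start0 = del_end0 = None
    del_len = (del_end0 - del_start0) if spec.deletion is not None else 0
    donor = ref[:del_start0] + ref[del_end0:] if spec.deletion is not None else ref
    if len(donor) < spec.read_length:
        raise ValidationError("donor genome shorter than read length")

    # SNP lookup in donor coordinates (SNPs never sit inside the deletion)
    snp_by_donor_pos: dict[int, tuple[str, float, int]] = {}
    for pos, alt, frac in spec.snps:
        p0 = pos - 1
        d0 = p0 if (del_start0 is None or p0 < del_start0) else p0 - del_len
        if ref[p0] == alt:
            raise ValidationError(f"SNP alt at {pos} equals the reference base {alt!r}")
        snp_by_donor_pos[d0] = (alt, frac, pos)

    L = spec.read_length
    n_reads = int(round(spec.mean_depth * (len(donor) - L + 1) / L))
    starts = np.sort(rng.integers(0, len(donor) - L + 1, size=n_reads))

    reads: list[SimulatedRead] = []
    for i, s in enumerate(starts):
        s = int(s)
        bases = list(donor[s:s + L])
        for d0, (alt, frac, _pos) in snp_by_donor_pos.items():
            if s <= d0 < s + L and rng.random() < frac:
                bases[d0 - s] = alt
        if spec.error_rate > 0:
            for k in range(L):
                if rng.random() < spec.error_rate:
                    bases[k] = _BASES[
                        (_BASES.index(bases[k]) + int(rng.integers(1, 4))) % 4
                    ]
        seq = "".join(bases)
        if del_start0 is not None and s < del_start0 < s + L:
            m1 = del_start0 - s
            cigar = [(0, m1), (2, del_len), (0, L - m1)]
            ref_start = s
        else:
            cigar = [(0, L)]
            ref_start = s if (del_start0 is None or s < del_start0) else s + del_len
        reads.append(SimulatedRead(f"read_{i + 1:06d}", ref_start, cigar, seq))

    truth_rows = [
        {"kind": "snp", "chrom": spec.chrom, "start": pos, "end": pos,
         "ref": ref[pos - 1], "alt": alt, "fraction": frac}
        for pos, alt, frac in spec.snps
    ]
    if spec.deletion is not None:
        truth_rows.append({
            "kind": "deletion", "chrom": spec.chrom,
            "start": spec.deletion[0], "end": spec.deletion[1],
            "ref": "", "alt": "", "fraction": 1.0,
        })
    truth = pd.DataFrame(
        truth_rows, columns=["kind", "chrom", "start", "end", "ref", "alt", "fraction"]
    )
    return ReadSimResult(ref, reads, truth)


def write_read_files(
    spec: ReadSimSpec, out_prefix: str | Path
) -> tuple[Path, Path, Path]:
    """Write ``<prefix>.fasta``, coordinate-sorted ``<prefix>.sam`` and the truth TSV."""
    result = simulate_reads(spec)
    out_prefix = Path(out_prefix)
    fasta_path = out_prefix.with_name(out_prefix.name + ".fasta")
    sam_path = out_prefix.with_name(out_prefix.name + ".sam")
    truth_path = out_prefix.with_name(out_prefix.name + ".truth.tsv")

    with open(fasta_path, "w", encoding="utf-8") as fh:
        fh.write(f">{spec.chrom}\n")
        for i in range(0, len(result.reference), 70):
            fh.write(result.reference[i:i + 70] + "\n")

    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": spec.chrom, "LN": spec.ref_length}],
        "RG": [{"ID": spec.sample, "SM": spec.sample}],
    }
    with pysam.AlignmentFile(str(sam_path), "w", header=header) as out:
        for read in result.reads:
            a = pysam.AlignedSegment(out.header)
            a.query_name = read.name
            a.query_sequence = read.sequence
            a.flag = 0
            a.reference_id = 0
            a.reference_start = read.ref_start
            a.mapping_quality = 60
            a.cigar = read.cigar
            a.query_qualities = pysam.qualitystring_to_array("I" * len(read.sequence))
            a.set_tag("RG", spec.sample)
            out.write(a)

    result.truth.to_csv(truth_path, sep="\t", index=False)
    return fasta_path, sam_path, truth_path


def make_annotation_fixtures(
    truth: pd.DataFrame,
    jitter: int = 0,
    decoys: int = 0,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Derive DGV-style and dbSNP-style tables from a truth table.

    CNV truth rows (aCGH truth, or read truth rows with kind == "deletion")
    become one catalogue record each, with endpoints independently jittered
    by up to ``jitter`` bp; SNP truth rows become dbSNP records.  ``decoys``
    adds that many records per table on the same chromosomes, placed beyond
    every truth interval so they can never overlap a real event.
    """
    if jitter < 0 or decoys < 0:
        raise ValidationError("jitter and decoys must be >= 0")
    rng = np.random.default_rng(seed)

    if "kind" in truth.columns:
        cnv_rows = truth[truth["kind"] == "deletion"]
        snp_rows = truth[truth["kind"] == "snp"]
    else:
        cnv_rows = truth
        snp_rows = truth.iloc[0:0]

    dgv_records = []
    seen: set[tuple[str, int, int]] = set()
    for _, row in cnv_rows.iterrows():
        key = (row["chrom"], int(row["start"]), int(row["end"]))
        if key in seen:  # one record per planted region, even if shared by samples
            continue
        seen.add(key)
        if "delta" in row and not pd.isna(row.get("delta")):
            vtype = "gain" if row["delta"] > 0 else "loss"
        else:
            vtype = "loss"
        start = max(1, key[1] + int(rng.integers(-jitter, jitter + 1)) if jitter else key[1])
        end = max(start, key[2] + int(rng.integers(-jitter, jitter + 1)) if jitter else key[2])
        dgv_records.append({
            "variant_id": f"dgv_{len(dgv_records) + 1}", "chrom": key[0],
            "start": start, "end": end, "variation_type": vtype,
            "genes": "", "reference": "synthetic",
        })

    snp_records = []
    for _, row in snp_rows.iterrows():
        snp_records.append({
            "rsid": f"rs{900000 + len(snp_records) + 1}", "chrom": row["chrom"],
            "pos": int(row["start"]), "alleles": f"{row['ref']}/{row['alt']}",
        })

    chroms = sorted(set(truth["chrom"])) if len(truth) else ["chr1"]
    horizon = int(truth["end"].max()) + 1 if len(truth) else 1
    for i in range(decoys):
        chrom = chroms[int(rng.integers(0, len(chroms)))]
        start = horizon + int(rng.integers(1000, 100_000))
        length = int(rng.integers(500, 5000))
        dgv_records.append({
            "variant_id": f"dgv_decoy_{i + 1}", "chrom": chrom,
            "start": start, "end": start + length,
            "variation_type": "gain" if rng.random() < 0.5 else "loss",
            "genes": "", "reference": "synthetic_decoy",
        })
        snp_records.append({
            "rsid": f"rs_decoy_{i + 1}", "chrom": chrom,
            "pos": horizon + int(rng.integers(1000, 100_000)),
            "alleles": "A/G",
        })

    dgv = pd.DataFrame(
        dgv_records,
        columns=["variant_id", "chrom", "start", "end", "variation_type", "genes", "reference"],
    )
    dbsnp = pd.DataFrame(snp_records, columns=["rsid", "chrom", "pos", "alleles"])
    return dgv, dbsnp


def write_annotation_fixtures(
    truth: pd.DataFrame, out_prefix: str | Path,
    jitter: int = 0, decoys: int = 0, seed: int = 0,
) -> tuple[Path, Path]:
    dgv, dbsnp = make_annotation_fixtures(truth, jitter=jitter, decoys=decoys, seed=seed)
    out_prefix = Path(out_prefix)
    dgv_path = out_prefix.with_name(out_prefix.name + ".dgv.tsv")
    dbsnp_path = out_prefix.with_name(out_prefix.name + ".dbsnp.tsv")
    dgv.to_csv(dgv_path, sep="\t", index=False)
    dbsnp.to_csv(dbsnp_path, sep="\t", index=False)
    return dgv_path, dbsnp_path
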