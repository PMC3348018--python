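"""Independent oracles used by the test suite and the acceptance script.

Everything here deliberately avoids the code paths it checks: the maximum
subarray sum is a quadratic scan, the annotation verdicts come from an
all-pairs overlap loop, the pileup is a from-scratch SAM text parser with its
own CIGAR walker, and the region summary is a two-pass computation in plain
Python.  Random SAM inputs are likewise emitted as hand-formatted text, not
through the library under test.
"""

from __future__ import annotations

import math
import re

_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")


def brute_max_subarray(scores) -> float:
    """Quadratic maximum contiguous subarray sum (empty subarray excluded)."""
    best = -math.inf
    n = len(scores)
    for i in range(n):
        total = 0.0
        for j in range(i, n):
            total += scores[j]
            if total > best:
                best = total
    return best


def quadratic_known_novel(segments, records, min_reciprocal: float) -> list[str]:
    """All-pairs known/novel verdicts on 1-based inclusive intervals.

    ``segments`` and ``records`` are (chrom, start, end) triples.
    """
    out = []
    for s_chrom, s_start, s_end in segments:
        known = False
        for r_chrom, r_start, r_end in records:
            if s_chrom != r_chrom:
                continue
            ov = min(s_end, r_end) - max(s_start, r_start) + 1
            if ov < 1:
                continue
            ro = min(ov / (s_end - s_start + 1), ov / (r_end - r_start + 1))
            if ro >= min_reciprocal:
                known = True
                break
        out.append("known" if known else "novel")
    return out


def two_pass_summary(values) -> dict:
    """Mean/median/max/min/sum/sample-variance computed without numpy."""
    xs = sorted(float(v) for v in values if not math.isnan(float(v)))
    n = len(xs)
    if n == 0:
        raise ValueError("no values")
    total = 0.0
    for v in xs:
        total += v
    mean = total / n
    if n % 2:
        median = xs[n // 2]
    else:
        median = (xs[n // 2 - 1] + xs[n // 2]) / 2.0
    if n > 1:
        ss = 0.0
        for v in xs:
            ss += (v - mean) ** 2
        variance = ss / (n - 1)
    else:
        variance = None
    return {"mean": mean, "median": median, "max": xs[-1], "min": xs[0],
            "sum": total, "variance": variance, "n": n}


def naive_sam_pileup(sam_text: str, chrom: str, start: int, end: int,
                     min_mapq: int = 0, min_baseq: int = 0) -> list[dict]:
    """Per-position base/DEL counts from raw SAM text, [start, end] 1-based.

    Skips unmapped (0x4), secondary (0x100), qc-fail (0x200) and duplicate
    (0x400) records and reads below ``min_mapq``; bases below ``min_baseq``
    (QUAL of '*' passes everything) are not counted.
    """
    n = end - start + 1
    cols = [{"A": 0, "C": 0, "G": 0, "T": 0, "N": 0, "DEL": 0} for _ in range(n)]
    for line in sam_text.splitlines():
        if not line or line.startswith("@"):
            continue
        f = line.split("\t")
        flag, rname, pos, mapq = int(f[1]), f[2], int(f[3]), int(f[4])
        cigar, seq, qual = f[5], f[9], f[10]
        if rname != chrom or flag & (0x4 | 0x100 | 0x200 | 0x400) or mapq < min_mapq:
            continue
        rp = pos  # 1-based reference pointer
        qp = 0
        for num, op in _CIGAR_RE.findall(cigar):
            length = int(num)
            if op in "M=X":
                for k in range(length):
                    p = rp + k
                    if start <= p <= end:
                        if qual != "*" and ord(qual[qp + k]) - 33 < min_baseq:
                            continue
                        base = seq[qp + k].upper()
                        cols[p - start][base if base in "ACGT" else "N"] += 1
                rp += length
                qp += length
            elif op == "D":
                for k in range(length):
                    p = rp + k
                    if start <= p <= end:
                        cols[p - start]["DEL"] += 1
                rp += length
            elif op == "N":
                rp += length
            elif op in "IS":
                qp += length
            # H, P: nothing
    return cols


def random_sam(rng, ref_name: str = "ref1", ref_len: int = 500,
               max_reads: int = 50) -> str:
    """A random, hand-formatted SAM file exercising M/I/D/S CIGARs and flags."""
    lines = [
        "@HD\tVN:1.6\tSO:coordinate",
        f"@SQ\tSN:{ref_name}\tLN:{ref_len}",
    ]
    reads = []
    n_reads = int(rng.integers(1, max_reads + 1))
    for i in range(n_reads):
        pos = int(rng.integers(1, ref_len))  # 1-based
        ops = []
        ref_used = 0
        if rng.random() < 0.3:
            ops.append((int(rng.integers(1, 6)), "S"))
        n_blocks = int(rng.integers(1, 4))
        for b in range(n_blocks):
            m = int(rng.integers(1, 30))
            ops.append((m, "M"))
            ref_used += m
            if b < n_blocks - 1:
                kind = rng.random()
                length = int(rng.integers(1, 8))
                if kind < 0.4:
                    ops.append((length, "D"))
                    ref_used += length
                elif kind < 0.7:
                    ops.append((length, "I"))
                else:
                    ops.append((length, "N"))
                    ref_used += length
        if rng.random() < 0.3:
            ops.append((int(rng.integers(1, 6)), "S"))
        if pos + ref_used - 1 > ref_len:  # keep alignment on the reference
            pos = max(1, ref_len - ref_used + 1)
            if pos + ref_used - 1 > ref_len:
                continue
        qlen = sum(length for length, op in ops if op in "MIS")
        seq = "".join(rng.choice(list("ACGTN"), size=qlen, p=[0.24, 0.24, 0.24, 0.24, 0.04]))
        qual = "".join(chr(33 + int(q)) for q in rng.integers(0, 42, size=qlen))
        flag = 0
        r = rng.random()
        if r < 0.05:
            flag |= 0x4
        elif r < 0.10:
            flag |= 0x100
        elif r < 0.15:
            flag |= 0x400
        elif r < 0.20:
            flag |= 0x200
        mapq = int(rng.integers(0, 61))
        cigar = "".join(f"{length}{op}" for length, op in ops)
        if flag & 0x4:
            reads.append((pos, f"r{i}\t{flag}\t*\t0\t0\t*\t*\t0\t0\t{seq}\t{qual}"))
        else:
            reads.append((pos, f"r{i}\t{flag}\t{ref_name}\t{pos}\t{mapq}\t{cigar}\t*\t0\t0\t{seq}\t{qual}"))
    reads.sort(key=lambda t: t[0])
    lines.extend(line for _, line in reads)
    return "\n".join(lines) + "\n"
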