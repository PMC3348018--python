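"""Shared fixtures: tiny in-memory datasets and synthetic file builders."""

from __future__ import annotations

import io
from pathlib import Path

import numpy as np
import pytest
from hypothesis import settings

from swcnv import AcghDataset, ProbeRecord

settings.register_profile("stable", derandomize=True, deadline=None)
settings.load_profile("stable")


def make_dataset(values, chrom="chr1", samples=None, spacing=100, probe_len=60):
    """A single-chromosome dataset from a value vector or (probe x sample) array."""
    values = np.atleast_2d(np.asarray(values, dtype=float))
    if values.shape[0] == 1 and values.shape[1] > 1 and (samples is None or len(samples) == 1):
        values = values.T
    n = values.shape[0]
    probes = [
        ProbeRecord(f"p{i + 1}", f"probe_{i + 1}", chrom,
                    1 + i * spacing, i * spacing + probe_len)
        for i in range(n)
    ]
    if samples is None:
        samples = [f"s{j + 1}" for j in range(values.shape[1])]
    return AcghDataset(probes, list(samples), values)


@pytest.fixture
def hand_profile():
    """The worked single-sample profile with one obvious gain."""
    return [0.1, -0.1, 1.0, 1.1, 0.9, 0.0, -0.2]


@pytest.fixture
def hand_dataset(hand_profile):
    return make_dataset(hand_profile)


@pytest.fixture
def acgh_text():
    """A minimal two-probe, one-sample aCGH file body (no header)."""
    return "p1\tp1n\tchr1\t100\t160\t0.10\np2\tp2n\tchr1\t200\t260\t-0.80\n"


def as_stream(text: str) -> io.StringIO:
    return io.StringIO(text)
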