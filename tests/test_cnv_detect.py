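"""Segmentation: MAD, Smith-Waterman islands, detection and the bin matrix."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from swcnv import (
    AcghEvent,
    AcghSimSpec,
    CnvParams,
    DegenerateDispersionError,
    ValidationError,
    detect_all,
    detect_cnv,
    mad,
    segment_matrix,
    simulate_acgh,
    sw_islands,
)

from conftest import make_dataset
from oracles import brute_max_subarray


class TestMad:
    @pytest.mark.parametrize("values, expected", [
        ([1, 1, 2, 2, 4], 1.0),
        ([3, 3, 3], 0.0),
        ([1, 2, 3, 4, 5, 6, 7, 8, 9], 2.0),  # deviations 4..0..4, median 2
        ([1, 2, 3, 4], 1.0),                 # even length: mean of central two
    ])
    def test_known_values(self, values, expected):
        assert mad(values) == pytest.approx(expected)

    def test_empty_and_nan_rejected(self):
        with pytest.raises(ValidationError):
            mad([])
        with pytest.raises(ValidationError):
            mad([1.0, math.nan])


class TestSwIslands:
    @pytest.mark.parametrize("scores, expected", [
        ([-1.0, -0.5, -2.0], []),
        ([], []),
        ([2.0], [(0, 0, 2.0)]),
        ([0.5, -0.2, 0.8, -1.0, 0.3], [(0, 2, pytest.approx(1.1))]),
        # two separate positive runs
        ([1.0, -5.0, 2.0, 0.5], [(0, 0, 1.0), (2, 3, 2.5)]),
        # a zero running score closes the run
        ([1.0, -1.0, 1.0], [(0, 0, 1.0), (2, 2, 1.0)]),
        # island ends at the FIRST argmax of the running score (leftmost tie)
        ([1.0, -0.5, 0.5], [(0, 0, 1.0)]),
    ])
    def test_examples(self, scores, expected):
        result = sw_islands(scores)
        assert len(result) == len(expected)
        for (s, e, sc), (es, ee, esc) in zip(result, expected):
            assert (s, e) == (es, ee)
            assert sc == pytest.approx(esc)

    @settings(max_examples=300, deadline=None)
    @given(st.lists(st.floats(-1, 1, allow_nan=False), max_size=60))
    def test_best_island_matches_brute_force_max_subarray(self, scores):
        """The top island score equals the maximum contiguous subarray sum."""
        islands = sw_islands(scores)
        best = brute_max_subarray(scores) if scores else -math.inf
        if best > 0:
            assert islands, "positive max subarray must yield an island"
            assert max(s for _, _, s in islands) == pytest.approx(best, abs=1e-9)
        else:
            assert islands == []

    @settings(max_examples=100, deadline=None)
    @given(st.lists(st.floats(-1, 1, allow_nan=False), max_size=60))
    def test_islands_disjoint_and_ordered(self, scores):
        islands = sw_islands(scores)
        for (s1, e1, _), (s2, e2, _) in zip(islands, islands[1:]):
            assert e1 < s2
        for s, e, sc in islands:
            assert s <= e and sc > 0


class TestDetectCnv:
    def test_hand_worked_gain(self, hand_dataset):
        """median 0.1, MAD 0.3, k=1 threshold 0.4 -> island over probes 2-4."""
        params = CnvParams(mad_multiplier=1.0, min_island_probes=2, direction="gain")
        segs = detect_cnv(hand_dataset, "s1", "chr1", params)
        assert len(segs) == 1
        seg = segs[0]
        assert (seg.first_probe_index, seg.last_probe_index) == (2, 4)
        assert seg.n_probes == 3
        assert seg.sw_score == pytest.approx(1.8)
        assert seg.segmental_mean == pytest.approx(1.0)
        assert seg.start == hand_dataset.probes[2].start
        assert seg.end == hand_dataset.probes[4].end

    def test_island_shorter_than_block_length_dropped(self, hand_dataset):
        params = CnvParams(mad_multiplier=1.0, min_island_probes=4, direction="gain")
        assert detect_cnv(hand_dataset, "s1", "chr1", params) == []

    def test_constant_signal_is_degenerate(self):
        ds = make_dataset([0.5] * 6)
        with pytest.raises(DegenerateDispersionError, match="degenerate"):
            detect_cnv(ds, "s1", "chr1", CnvParams())

    def test_abs_threshold_rescues_constant_dispersion(self):
        values = [0.0] * 10 + [1.0] * 6 + [0.0] * 10
        ds = make_dataset(values)
        # MAD is 0 here (most probes identical), abs_threshold takes over
        params = CnvParams(mad_multiplier=3.0, min_island_probes=3,
                           direction="gain", abs_threshold=0.5)
        segs = detect_cnv(ds, "s1", "chr1", params)
        assert [(s.first_probe_index, s.last_probe_index) for s in segs] == [(10, 15)]

    def test_missing_values_do_not_break_islands(self):
        values = [0.0, 0.0, 1.0, math.nan, 1.0, 1.1, 0.0, 0.0, -0.1, 0.1]
        ds = make_dataset(values)
        params = CnvParams(mad_multiplier=2.0, min_island_probes=3, direction="gain")
        segs = detect_cnv(ds, "s1", "chr1", params)
        assert len(segs) == 1
        assert (segs[0].first_probe_index, segs[0].last_probe_index) == (2, 5)
        assert segs[0].n_probes == 4  # includes the missing probe inside the span

    def test_unknown_sample_or_chrom(self, hand_dataset):
        with pytest.raises(ValidationError):
            detect_cnv(hand_dataset, "nope", "chr1", CnvParams())
        with pytest.raises(ValidationError):
            detect_cnv(hand_dataset, "s1", "chr9", CnvParams())

    def test_gain_loss_symmetry(self):
        """Negating the profile and swapping direction yields identical segments."""
        rng = np.random.default_rng(11)
        values = rng.normal(0, 0.2, size=80)
        values[20:32] += 1.0
        ds_pos = make_dataset(values)
        ds_neg = make_dataset(-values)
        p_gain = CnvParams(mad_multiplier=2.0, min_island_probes=3, direction="gain")
        p_loss = CnvParams(mad_multiplier=2.0, min_island_probes=3, direction="loss")
        gains = detect_cnv(ds_pos, "s1", "chr1", p_gain)
        losses = detect_cnv(ds_neg, "s1", "chr1", p_loss)
        assert len(gains) == len(losses) > 0
        for g, l in zip(gains, losses):
            assert (g.start, g.end, g.n_probes) == (l.start, l.end, l.n_probes)
            assert g.sw_score == pytest.approx(l.sw_score, abs=1e-9)
            assert g.segmental_mean == pytest.approx(-l.segmental_mean, abs=1e-9)

    @pytest.mark.parametrize("vary", ["k", "L"])
    def test_strictness_monotonicity(self, vary):
        """Raising k or L never adds segments; survivors nest in looser spans."""
        rng = np.random.default_rng(7)
        values = rng.normal(0, 0.2, size=150)
        values[30:45] += 0.8
        values[90:100] -= 0.9
        ds = make_dataset(values)
        settings_list = (
            [CnvParams(mad_multiplier=k, min_island_probes=5) for k in (1.0, 2.0, 3.0, 4.0)]
            if vary == "k"
            else [CnvParams(mad_multiplier=2.0, min_island_probes=L) for L in (2, 5, 8, 12)]
        )
        runs = [detect_cnv(ds, "s1", "chr1", p) for p in settings_list]
        for loose, strict in zip(runs, runs[1:]):
            assert len(strict) <= len(loose)
            for s in strict:
                assert any(
                    g.first_probe_index <= s.first_probe_index
                    and s.last_probe_index <= g.last_probe_index
                    and g.type == s.type
                    for g in loose
                )


class TestDetectAll:
    def test_one_planted_gain_per_chromosome(self):
        spec = AcghSimSpec(
            probes_per_chrom={"chr1": 60, "chr2": 60}, noise_sd=0.15, seed=5,
            events=(AcghEvent("chr1", 20, 34, 1.0), AcghEvent("chr2", 10, 24, -1.0)),
        )
        ds, _ = simulate_acgh(spec)
        result = detect_all(ds, CnvParams(mad_multiplier=3.0, min_island_probes=5))
        segs = result.all_segments()
        assert {(s.chrom, s.type) for s in segs} == {("chr1", "gain"), ("chr2", "loss")}
        assert result.issues == []

    def test_flat_dataset_reports_degenerate_issues_not_errors(self):
        ds = make_dataset(np.zeros((20, 2)), samples=["a", "b"])
        result = detect_all(ds, CnvParams())
        assert result.all_segments() == []
        assert len(result.issues) == 2  # one per sample on the single chromosome
        assert all("degenerate" in msg for _, _, msg in result.issues)

    def test_planted_gain_recovered_with_high_reciprocal_overlap(self):
        spec = AcghSimSpec(probes_per_chrom={"chr1": 120}, noise_sd=0.15, seed=42,
                           events=(AcghEvent("chr1", 50, 59, 1.0),))
        ds, truth = simulate_acgh(spec)
        segs = detect_cnv(ds, "sample_1", "chr1",
                          CnvParams(mad_multiplier=3.0, min_island_probes=5, direction="gain"))
        assert len(segs) == 1
        t = truth.iloc[0]
        ov = min(segs[0].end, t.end) - max(segs[0].start, t.start) + 1
        ro = min(ov / (segs[0].end - segs[0].start + 1), ov / (t.end - t.start + 1))
        assert ro >= 0.9


class TestSegmentMatrix:
    def _seg(self, sample, start, end, type="gain", chrom="chr1"):
        from swcnv import CnvSegment
        return CnvSegment(sample=sample, chrom=chrom, start=start, end=end,
                          first_probe_index=0, last_probe_index=0, type=type,
                          sw_score=1.0, segmental_mean=1.0 if type == "gain" else -1.0,
                          n_probes=5)

    def test_full_bins_take_segment_type(self):
        segs = {"s1": [self._seg("s1", 301, 600)]}
        matrix, bins = segment_matrix(segs, "chr1", bin_size=100)
        assert list(matrix.loc["s1"]) == ["neutral"] * 3 + ["gain"] * 3
        assert bins["start"].tolist() == [1, 101, 201, 301, 401, 501]

    def test_forty_percent_coverage_stays_neutral(self):
        segs = {"s1": [self._seg("s1", 101, 140)]}  # 40 bp of bin 2
        matrix, _ = segment_matrix(segs, "chr1", bin_size=100)
        assert list(matrix.loc["s1"]) == ["neutral", "neutral"]

    def test_two_samples_disjoint_segments(self):
        segs = {"a": [self._seg("a", 1, 100)], "b": [self._seg("b", 201, 300, type="loss")]}
        matrix, _ = segment_matrix(segs, "chr1", bin_size=100)
        assert list(matrix.loc["a"]) == ["gain", "neutral", "neutral"]
        assert list(matrix.loc["b"]) == ["neutral", "neutral", "loss"]

    def test_gain_and_loss_in_same_bin_conflict(self):
        segs = {"s1": [self._seg("s1", 1, 60), self._seg("s1", 41, 100, type="loss")]}
        matrix, _ = segment_matrix(segs, "chr1", bin_size=100)
        assert list(matrix.loc["s1"]) == ["conflict"]

    def test_bad_bin_size(self):
        with pytest.raises(ValidationError):
            segment_matrix({}, "chr1", 0)
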