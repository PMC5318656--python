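"""Window binning, RPM arithmetic, island calling, merging and ranking."""

from __future__ import annotations

import re

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst
from scipy import stats as sps

from gammamap.core import GammaRegion, GenomicInterval, TagLibrary, WindowTrack
from gammamap.regions import (IslandParams, bin_tags, call_islands,
                              condition_specific_regions, merge_region_lists,
                              normalize_region, rank_regions, region_metrics,
                              rpm, _eligible, _island_spans)


def make_track(counts, window, chrom_size, total=None):
    counts = np.asarray(counts, dtype=np.int64)
    return WindowTrack(window=window, counts={"chr1": counts},
                       chrom_sizes={"chr1": chrom_size},
                       total=int(counts.sum()) if total is None else total)


class TestBinTags:
    @pytest.mark.parametrize("positions, window, expected", [
        ([5, 50, 150], 100, [2, 1]),
        ([100], 100, [0, 1]),          # half-open: position 100 -> window 1
        ([0, 99, 199], 100, [2, 1]),
    ])
    def test_window_counts(self, positions, window, expected):
        lib = TagLibrary({"chr1": positions})
        track = bin_tags(lib, window, {"chr1": 200})
        assert track.counts["chr1"].tolist() == expected
        assert track.total == len(positions)

    def test_empty_library_zero_track(self):
        track = bin_tags(TagLibrary({"chr1": []}), 100, {"chr1": 1000})
        assert track.counts["chr1"].sum() == 0
        assert track.lambda_bg == 0.0

    def test_partial_last_window_kept(self):
        track = bin_tags(TagLibrary({"chr1": [249]}), 100, {"chr1": 250})
        assert len(track.counts["chr1"]) == 3

    def test_invalid_window_rejected(self):
        with pytest.raises(ValueError):
            bin_tags(TagLibrary({"chr1": [1]}), 0, {"chr1": 100})

    def test_lambda_matches_definition(self):
        lib = TagLibrary({"chr1": list(range(0, 1000, 10))})
        track = bin_tags(lib, 100, {"chr1": 1000})
        assert track.lambda_bg == pytest.approx(100 * 100 / 1000)


class TestRpm:
    @pytest.mark.parametrize("count, total, expected", [
        (100, 10**6, 100.0), (0, 123, 0.0), (250, 5 * 10**6, 50.0),
    ])
    def test_values(self, count, total, expected):
        assert rpm(count, total) == pytest.approx(expected)

    def test_zero_total_raises(self):
        with pytest.raises(ValueError):
            rpm(10, 0)


def oracle_island_spans(eligible, gap):
    """Independent run enumeration: regex over the eligibility bitstring."""
    bits = "".join("1" if e else "0" for e in eligible)
    spans = []
    for m in re.finditer(rf"1(?:0{{0,{gap}}}1)*", bits):
        spans.append((m.start(), m.end() - 1))
    return spans


class TestCallIslands:
    def setup_method(self):
        # background fixed at lambda_bg = 1 (total=5, W=100, genome 500 bp)
        # so count >= 5 is eligible at p0=0.01 and 0 is not
        self.chip = make_track([5, 5, 0, 0, 5], 100, 500, total=5)
        self.ctrl = make_track([1, 1, 1, 1, 1], 100, 500)
        self.params = dict(window=100, p0=0.01, fc_min=2.0, fdr_max=0.1)

    def test_gap_one_gives_two_islands(self):
        islands = call_islands(self.chip, self.ctrl,
                               IslandParams(gap=1, **self.params))
        spans = [(r.interval.start, r.interval.end) for r in islands]
        assert spans == [(0, 200), (400, 500)]

    def test_gap_two_fuses_into_one(self):
        islands = call_islands(self.chip, self.ctrl,
                               IslandParams(gap=2, **self.params))
        assert [(r.interval.start, r.interval.end) for r in islands] \
            == [(0, 500)]

    def test_island_score_is_sum_of_window_logp(self):
        islands = call_islands(self.chip, self.ctrl,
                               IslandParams(gap=1, **self.params))
        lam = self.chip.lambda_bg
        expected = -2 * sps.poisson.logsf(4, lam)
        assert islands[0].score == pytest.approx(expected)

    def test_chip_equal_control_retains_nothing(self, rng):
        counts = rng.poisson(5.0, size=200)
        chip = make_track(counts, 100, 20_000)
        ctrl = make_track(counts.copy(), 100, 20_000)
        islands = call_islands(chip, ctrl, IslandParams(
            window=100, p0=0.2, fc_min=2.0, fdr_max=0.05))
        assert islands == []

    def test_mismatched_windows_rejected(self):
        with pytest.raises(ValueError):
            call_islands(self.chip, make_track([1] * 10, 50, 500),
                         IslandParams(window=100))

    @pytest.mark.parametrize("gap", range(6))
    def test_span_fusion_matches_run_enumeration(self, gap, rng):
        for _ in range(20):
            eligible = rng.random(200) < 0.3
            got = _island_spans(eligible, gap)
            assert got == oracle_island_spans(eligible, gap)


class TestNormalizeRegion:
    def test_nrpm_is_difference(self):
        # 10 chip tags vs 2 control tags in [0, 100), totals 1e6 each
        chip = TagLibrary({"chr1": list(range(10))})
        ctrl = TagLibrary({"chr1": [0, 1]})
        chip_total, ctrl_total = 10**6, 10**6
        vals = region_metrics(10, 2, chip_total, ctrl_total, 100)
        assert vals[2] == pytest.approx(10.0 - 2.0)
        del chip, ctrl

    def test_rpkm_definition(self):
        # 500 reads on 10 kb with a 50 M-read library -> 1.0
        _, _, _, _, rpkm_ = region_metrics(500, 0, 50_000_000, 1, 10_000)
        assert rpkm_ == pytest.approx(1.0)

    def test_pseudocount_fold_change(self):
        _, _, _, fc, _ = region_metrics(9, 0, 1000, 1000, 100, pseudo=1.0)
        assert fc == pytest.approx(10.0)

    def test_counts_from_libraries(self):
        chip = TagLibrary({"chr1": [10, 20, 30, 150]})
        ctrl = TagLibrary({"chr1": [5, 160]})
        iv = GenomicInterval("chr1", 0, 100)
        chip_rpm, ctrl_rpm, nrpm, fc, _ = normalize_region(iv, chip, ctrl)
        assert chip_rpm == pytest.approx(3 * 1e6 / 4)
        assert ctrl_rpm == pytest.approx(1 * 1e6 / 2)
        assert nrpm == pytest.approx(chip_rpm - ctrl_rpm)
        assert fc == pytest.approx((3 + 1) / (1 * 4 / 2 + 1))


def iv(chrom, start, end):
    return GenomicInterval(chrom, start, end)


intervals_strategy = hst.lists(
    hst.tuples(hst.sampled_from(["chr1", "chr2"]),
               hst.integers(0, 5000), hst.integers(1, 500)),
    min_size=0, max_size=30)


def disjoint(ivs):
    out = []
    for c, s, ln in sorted(ivs):
        if out and out[-1].chrom == c and s <= out[-1].end:
            s = out[-1].end + 1
        out.append(GenomicInterval(c, s, s + ln))
    return out


class TestMergeRegionLists:
    def test_identical_lists_all_common(self):
        a = [iv("chr1", 100, 200), iv("chr1", 500, 700)]
        merged = merge_region_lists(a, list(a))
        assert len(merged) == len(a)
        assert all(m.is_common for m in merged)

    def test_disjoint_lists_sum(self):
        a = [iv("chr1", 100, 200)]
        b = [iv("chr1", 500, 700), iv("chr2", 0, 50)]
        merged = merge_region_lists(a, b)
        assert len(merged) == 3
        assert not any(m.is_common for m in merged)

    def test_overlap_fuses_to_union(self):
        merged = merge_region_lists([iv("chr1", 100, 200)],
                                    [iv("chr1", 150, 250)])
        assert len(merged) == 1
        assert (merged[0].interval.start, merged[0].interval.end) == (100, 250)
        assert merged[0].is_common

    def test_bookended_intervals_fuse(self):
        merged = merge_region_lists([iv("chr1", 0, 100)],
                                    [iv("chr1", 100, 200)])
        assert len(merged) == 1

    @given(intervals_strategy, intervals_strategy)
    @settings(max_examples=60, deadline=None)
    def test_properties(self, raw_a, raw_b):
        a, b = disjoint(raw_a), disjoint(raw_b)
        ab = merge_region_lists(a, b)
        # commutativity on intervals and common flags
        ba = merge_region_lists(b, a)
        assert [(m.interval.sort_key(), m.is_common) for m in ab] \
            == [(m.interval.sort_key(), m.is_common) for m in ba]
        # output never overlaps and is bounded by |A| + |B|
        for x, y in zip(ab, ab[1:]):
            if x.interval.chrom == y.interval.chrom:
                assert y.interval.start > x.interval.end
        assert len(ab) <= len(a) + len(b)
        # idempotence
        again = merge_region_lists(ab, ab)
        assert [m.interval.sort_key() for m in again] \
            == [m.interval.sort_key() for m in ab]


def region(chrom, start, end, fc, nrpm=0.0):
    return GammaRegion(interval=GenomicInterval(chrom, start, end), fc=fc,
                       nrpm=nrpm)


class TestRankRegions:
    def test_descending_fc_on_distinct_genes(self):
        regs = [region("chr1", 0, 10, 8), region("chr1", 20, 30, 2),
                region("chr1", 40, 50, 5)]
        df = rank_regions(regs, [["gA"], ["gB"], ["gC"]])
        assert df.genes.tolist() == ["gA", "gC", "gB"]
        assert df.fc.tolist() == [8, 5, 2]

    def test_shared_gene_rows_average(self):
        regs = [region("chr1", 0, 10, 4), region("chr1", 20, 30, 6)]
        df = rank_regions(regs, [["gA"], ["gA"]])
        assert len(df) == 1
        assert df.fc.iloc[0] == pytest.approx(5.0)
        assert df.n_regions.iloc[0] == 2

    def test_ties_fall_back_to_coordinate(self):
        regs = [region("chr1", 40, 50, 3), region("chr1", 0, 10, 3),
                region("chr1", 20, 30, 3)]
        df = rank_regions(regs, [["gC"], ["gA"], ["gB"]])
        assert df.start.tolist() == [0, 20, 40]


class TestConditionSpecific:
    def test_specific_region_retained_and_shared_excluded(self):
        # region 1: A-specific signal; region 2: equal in A and B
        chip_a = TagLibrary({"chr1": list(range(0, 100)) * 1
                             + list(range(1000, 1050))})
        chip_b = TagLibrary({"chr1": list(range(1000, 1050))
                             + list(range(5000, 5100))})
        ctrl = TagLibrary({"chr1": list(range(8000, 8100))})
        regs = [iv("chr1", 0, 100), iv("chr1", 1000, 1100)]
        df = condition_specific_regions(regs, chip_a, chip_b, ctrl,
                                        min_fc_ab=2.0, eps=1.0)
        assert df.start.tolist() == [0]

    def test_negative_nrpm_floored(self):
        chip_a = TagLibrary({"chr1": [500]})
        chip_b = TagLibrary({"chr1": [5000]})
        ctrl = TagLibrary({"chr1": list(range(0, 100))})
        df = condition_specific_regions([iv("chr1", 0, 200)], chip_a, chip_b,
                                        ctrl, min_fc_ab=0.0, eps=1.0)
        # both nrpm negative -> floored, cross FC exactly 1
        assert df.cross_fc.iloc[0] == pytest.approx(1.0)
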