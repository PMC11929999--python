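"""CNVR assembly: density trimming, consensus, sharing, exclusivity."""

from __future__ import annotations

import numpy as np
import pytest

from cnvrpipe.calls import CnvCall
from cnvrpipe.cnvr import (
    build_tool_cnvrs,
    consensus_cnvrs,
    exclusive_cnvrs,
    shared_cnvrs,
    summarize_cnvrs,
)
from cnvrpipe.intervals import Interval
from cnvrpipe.samples import SampleSheet


def mk_call(chrom="1", start=1000, end=1999, cnv_type="loss", sample="s1",
            tool="paired_split", cn=None):
    return CnvCall(sample, tool, chrom, start, end, cnv_type, cn)


def trim_oracle(calls, density_min):
    """Per-base recomputation of merge + density trimming for one type.

    Counts coverage at every base of each 1-bp-merged candidate region and
    keeps maximal runs with coverage >= density_min * n_contributing.
    """
    from cnvrpipe.intervals import merge_adjacent

    pieces = []
    for region in merge_adjacent([c.interval for c in calls]):
        contrib = [
            c for c in calls
            if c.chrom == region.chrom and c.start <= region.end and c.end >= region.start
        ]
        cov = np.zeros(region.end - region.start + 1, dtype=int)
        for c in contrib:
            cov[max(c.start, region.start) - region.start:
                min(c.end, region.end) - region.start + 1] += 1
        keep = cov >= density_min * len(contrib) - 1e-12
        i = 0
        while i < len(keep):
            if keep[i]:
                j = i
                while j + 1 < len(keep) and keep[j + 1]:
                    j += 1
                pieces.append(Interval(region.chrom, region.start + i, region.start + j))
                i = j + 1
            else:
                i += 1
    return pieces


class TestBuildToolCnvrs:
    def test_overlapping_losses_form_one_loss_region(self):
        calls = [mk_call(start=1000 + 10 * i, end=2000 + 10 * i, sample=f"s{i}")
                 for i in range(10)]
        cnvrs = build_tool_cnvrs(calls)
        assert len(cnvrs) == 1
        assert cnvrs[0].cnvr_type == "loss"
        assert len(cnvrs[0].samples) == 10

    def test_low_support_flank_is_trimmed(self):
        # 20 calls stacked on [10_000, 19_999]; one call extends a 1-kb flank
        # covered by 1/21 of contributing calls (< 10%): flank removed
        stack = [mk_call(start=10_000, end=19_999, sample=f"s{i}") for i in range(20)]
        flank = [mk_call(start=9_000, end=19_999, sample="s20")]
        cnvrs = build_tool_cnvrs(stack + flank, density_min=0.10)
        assert len(cnvrs) == 1
        assert cnvrs[0].span == Interval("1", 10_000, 19_999)

    def test_interior_gap_splits_region(self):
        left = [mk_call(start=1000, end=4999, sample=f"s{i}") for i in range(10)]
        right = [mk_call(start=8000, end=11_999, sample=f"s{i}") for i in range(10)]
        bridge = [mk_call(start=1000, end=11_999, sample="s99")]
        cnvrs = build_tool_cnvrs(left + right + bridge, density_min=0.10)
        assert [c.span for c in cnvrs] == [
            Interval("1", 1000, 4999), Interval("1", 8000, 11_999)
        ]

    def test_overlapping_loss_and_gain_fuse_to_both(self):
        loss = [mk_call(start=1, end=500, sample=f"s{i}") for i in range(3)]
        gain = [mk_call(start=400, end=900, cnv_type="gain", sample=f"s{i}")
                for i in range(3)]
        cnvrs = build_tool_cnvrs(loss + gain)
        assert len(cnvrs) == 1
        assert cnvrs[0].cnvr_type == "both"
        assert cnvrs[0].span == Interval("1", 1, 900)

    def test_mixed_tool_input_fatal(self):
        with pytest.raises(ValueError, match="one tool"):
            build_tool_cnvrs([mk_call(tool="a"), mk_call(tool="b")])

    def test_matches_per_base_oracle_on_random_input(self):
        rng = np.random.default_rng(17)
        for _ in range(20):
            calls = []
            for i in range(int(rng.integers(3, 30))):
                s = int(rng.integers(1, 3000))
                calls.append(mk_call(start=s, end=s + int(rng.integers(20, 500)),
                                     sample=f"s{i}"))
            got = [c.span for c in build_tool_cnvrs(calls, 0.10)]
            assert sorted(got) == sorted(trim_oracle(calls, 0.10))

    def test_trimming_is_a_fixed_point(self):
        rng = np.random.default_rng(23)
        calls = [mk_call(start=int(s), end=int(s) + 300, sample=f"s{i}")
                 for i, s in enumerate(rng.integers(1, 2000, size=15))]
        first = build_tool_cnvrs(calls, 0.10)
        spans = {c.span for c in first}
        again = build_tool_cnvrs(calls, 0.10)
        assert {c.span for c in again} == spans


class TestConsensus:
    def tool_set(self, tool, start, end, cnv_type="loss", n=3):
        calls = [mk_call(start=start, end=end, cnv_type=cnv_type,
                         sample=f"{tool}_s{i}", tool=tool) for i in range(n)]
        return build_tool_cnvrs(calls)

    def test_one_bp_overlap_across_two_tools_combines(self):
        a = self.tool_set("toolA", 1000, 2000)
        b = self.tool_set("toolB", 2000, 3000)  # shares exactly base 2000
        combined = consensus_cnvrs([a, b], min_tools=2)
        assert len(combined) == 1
        assert combined[0].span == Interval("1", 1000, 3000)
        assert combined[0].tools == {"toolA", "toolB"}

    def test_single_tool_region_discarded(self):
        a = self.tool_set("toolA", 1000, 2000)
        b = self.tool_set("toolB", 50_000, 60_000)
        assert consensus_cnvrs([a, b], min_tools=2) == []

    def test_opposite_types_do_not_rescue_each_other(self):
        a = self.tool_set("toolA", 1000, 2000, "gain")
        b = self.tool_set("toolB", 1500, 2500, "loss")
        assert consensus_cnvrs([a, b], min_tools=2) == []

    def test_both_type_bridges_either_type(self):
        calls_a = [mk_call(start=1000, end=2000, sample=f"s{i}", tool="toolA")
                   for i in range(3)]
        calls_a += [mk_call(start=1900, end=2600, cnv_type="gain",
                            sample=f"s{i}", tool="toolA") for i in range(3)]
        a = build_tool_cnvrs(calls_a)
        assert [r.cnvr_type for r in a] == ["both"]
        b = self.tool_set("toolB", 2400, 3000, "gain")
        combined = consensus_cnvrs([a, b], min_tools=2)
        assert len(combined) == 1
        assert combined[0].cnvr_type == "both"

    def test_min_tools_respected(self):
        a = self.tool_set("toolA", 1000, 2000)
        with pytest.raises(ValueError):
            consensus_cnvrs([a], min_tools=2)
        combined = consensus_cnvrs([a, self.tool_set("toolB", 1500, 2500)], 2)
        assert all(len(r.tools) >= 2 for r in combined)


@pytest.fixture
def small_sheet():
    return SampleSheet((
        ("a1", "BreedA", "America"), ("a2", "BreedA", "America"),
        ("a3", "BreedA", "America"),
        ("b1", "BreedB", "Europe"), ("b2", "BreedB", "Europe"),
    ))


class TestSharing:
    def consensus_for(self, samples, start=1000, end=2000):
        sets = []
        for tool in ("toolA", "toolB"):
            calls = [mk_call(start=start, end=end, sample=s, tool=tool)
                     for s in samples]
            sets.append(build_tool_cnvrs(calls))
        return consensus_cnvrs(sets, 2)

    def test_two_per_breed_required_everywhere(self, small_sheet):
        consensus = self.consensus_for(["a1", "a2", "b1", "b2"])
        calls = [mk_call(start=1000, end=2000, sample=s, tool="toolA")
                 for s in ("a1", "a2", "b1", "b2")]
        res = shared_cnvrs(consensus, calls, small_sheet, "per_breed_min2")
        assert len(res.kept) == 1
        # drop one European supporter -> BreedB has 1 < 2
        calls_minus = [c for c in calls if c.sample_id != "b2"]
        res2 = shared_cnvrs(consensus, calls_minus, small_sheet, "per_breed_min2")
        assert res2.kept == ()

    def test_region_all_requires_every_animal(self, small_sheet):
        consensus = self.consensus_for(["a1", "a2", "a3"])
        calls = [mk_call(start=1000, end=2000, sample=s, tool="toolA")
                 for s in ("a1", "a2", "a3")]
        res = shared_cnvrs(consensus, calls, small_sheet, "region_all",
                           region="America")
        assert len(res.kept) == 1
        res2 = shared_cnvrs(consensus, calls[:-1], small_sheet, "region_all",
                            region="America")
        assert res2.kept == ()

    def test_singletons_and_doubletons_reported_not_kept(self, small_sheet):
        consensus = self.consensus_for(["a1"])
        calls = [mk_call(start=1000, end=2000, sample="a1", tool="toolA")]
        res = shared_cnvrs(consensus, calls, small_sheet, "per_breed_min2")
        assert res.kept == () and len(res.singletons) == 1
        consensus2 = self.consensus_for(["a1", "b1"])
        calls2 = [mk_call(start=1000, end=2000, sample=s, tool="toolA")
                  for s in ("a1", "b1")]
        res2 = shared_cnvrs(consensus2, calls2, small_sheet, "per_breed_min2")
        assert res2.kept == () and len(res2.doubletons) == 1

    def test_underpowered_breed_fatal(self):
        sheet = SampleSheet((("a1", "BreedA", "America"),))
        with pytest.raises(ValueError, match="fewer than 2"):
            shared_cnvrs([], [], sheet, "per_breed_min2")


class TestExclusive:
    def region(self, start, end, tool="toolA"):
        calls = [mk_call(start=start, end=end, sample=f"s{i}", tool=t)
                 for i in range(2) for t in ("toolA", "toolB")]
        return consensus_cnvrs(
            [build_tool_cnvrs([c for c in calls if c.tool == t])
             for t in ("toolA", "toolB")], 2)[0]

    def test_one_bp_overlap_disqualifies(self):
        target = [self.region(1000, 2000)]
        other = [self.region(2000, 3000)]
        assert exclusive_cnvrs(target, [other]) == []

    def test_disjoint_kept_whole(self):
        target = [self.region(1000, 2000)]
        other = [self.region(5000, 6000)]
        assert exclusive_cnvrs(target, [other]) == target

    def test_identical_sets_empty_result(self):
        target = [self.region(1000, 2000)]
        assert exclusive_cnvrs(target, [list(target)]) == []

    def test_pairwise_disjoint_by_construction(self, default_run):
        regions = list(default_run.exclusive_by_region)
        for i, r1 in enumerate(regions):
            for r2 in regions[i + 1:]:
                for a in default_run.exclusive_by_region[r1]:
                    for b in default_run.exclusive_by_region[r2]:
                        assert (a.span.chrom != b.span.chrom
                                or a.span.end < b.span.start
                                or b.span.end < a.span.start)


class TestSummaries:
    def test_partition_identity_and_moments(self, toy_build):
        calls = [mk_call(start=1000, end=1999, sample=f"s{i}") for i in range(3)]
        cnvrs = build_tool_cnvrs(calls)
        s = summarize_cnvrs(cnvrs, toy_build)
        assert s.n_total == s.n_gain + s.n_loss + s.n_both == 1
        assert s.total_bp == 1000
        assert s.mean_length == 1000.0
        assert s.genome_fraction_pct == round(100 * 1000 / 30_000_000, 2)

    def test_empty_set_all_zero(self, toy_build):
        s = summarize_cnvrs([], toy_build)
        assert s.n_total == 0 and s.total_bp == 0 and s.genome_fraction_pct == 0.0
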