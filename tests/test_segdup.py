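"""WGAC self-comparison and WSSD read-depth duplication detection."""

import pytest

from asmrecon.core import BedInterval, ToolConfig
from asmrecon.segdup import (compare_wgac_wssd, nonredundant_bp, wgac_calls_at,
                             wgac_self_compare, wssd_call, wssd_depth)
from asmrecon.simulate import DupSpec, SimConfig, make_genome
from conftest import asm_from


@pytest.fixture(scope="module")
def wgac_result():
    from asmrecon.pipeline import wgac_metrics
    return wgac_metrics(seed=2, genome_len=400_000)


class TestWgac:
    def test_length_and_identity_thresholds(self, wgac_result):
        assert wgac_result["called_2kbp_98"]
        assert not wgac_result["called_800bp_98"]     # below 1 kbp
        assert not wgac_result["called_2kbp_85"]      # below 90% identity

    def test_detected_identity_close_to_planted(self, wgac_result):
        assert wgac_result["detected_identity"] == pytest.approx(0.98,
                                                                 abs=0.01)

    def test_mirror_symmetry(self):
        cfg = SimConfig(genome_len=300_000, seed=8,
                        duplications=[DupSpec(3000, 0.97)])
        genome, _ = make_genome(cfg)
        calls, nr = wgac_self_compare(genome, [], ToolConfig())
        keys = {(c.scaffold, c.start, c.end, c.mate) for c in calls}
        for c in calls:
            assert (c.mate[0], c.mate[1], c.mate[2],
                    (c.scaffold, c.start, c.end)) in keys

    def test_duplication_free_genome_yields_no_calls(self):
        genome, _ = make_genome(SimConfig(genome_len=1_000_000, seed=13))
        calls, nr = wgac_self_compare(genome, [], ToolConfig())
        assert calls == []

    def test_reverse_strand_duplication_found(self):
        cfg = SimConfig(genome_len=300_000, seed=9,
                        duplications=[DupSpec(3000, 0.98, strand="-")])
        genome, feats = make_genome(cfg)
        calls, _ = wgac_self_compare(genome, [], ToolConfig())
        assert calls and all(c.mate_strand == "-" for c in calls)


class TestNonredundant:
    def test_overlapping_calls_counted_once(self):
        asm = asm_from({"c": "A" * 2000})
        nr = {"c": [(0, 1000), (500, 1500)]}
        # merge happens upstream; feed the raw union here
        from asmrecon.core import merge_intervals
        bp, frac = nonredundant_bp({"c": merge_intervals(nr["c"])}, asm)
        assert bp == 1500

    def test_empty_and_fraction_arithmetic(self):
        asm = asm_from({"c": "A" * 1_000_000})
        assert nonredundant_bp({}, asm) == (0, 0.0)
        bp, frac = nonredundant_bp({"c": [(0, 40_000)]}, asm)
        assert (bp, frac) == (40_000, pytest.approx(0.04))

    def test_gap_bases_excluded_from_denominator(self):
        asm = asm_from({"c": "A" * 900_000 + "N" * 100_000})
        bp, frac = nonredundant_bp({"c": [(0, 45_000)]}, asm)
        assert frac == pytest.approx(0.05)


class _P:
    def __init__(self, scaffold, start, end, identity):
        self.scaffold, self.start, self.end = scaffold, start, end
        self.identity = identity


class TestWssd:
    def test_low_identity_reads_excluded_from_depth(self):
        asm = asm_from({"c": "ACGT" * 75_000})
        # uniform 10x at high identity + extra 10x at 90% over one region
        placements = []
        for s in range(0, 300_000 - 100, 10):
            placements.append(_P("c", s, s + 100, 0.99))
        for s in range(100_000, 120_000, 10):
            placements.append(_P("c", s, s + 100, 0.90))
        profile = wssd_depth(placements, asm,
                             [BedInterval("c", 0, 300_000)], ToolConfig())
        assert wssd_call(profile, ToolConfig()) == []

    def test_collapsed_duplication_called_with_tight_bounds(self):
        from asmrecon.pipeline import wssd_metrics

        m = wssd_metrics(seed=2, genome_len=800_000)
        assert m["big_reciprocal_overlap"] >= 0.9
        assert not m["small_called"]

    def test_null_genome_produces_no_calls(self):
        from asmrecon.pipeline import wssd_null_calls

        assert wssd_null_calls(seed=2) == 0

    def test_calibration_needs_enough_unique_windows(self):
        asm = asm_from({"c": "ACGT" * 10_000})
        placements = [_P("c", s, s + 100, 0.99) for s in range(0, 39_900, 10)]
        with pytest.raises(ValueError, match="calibration"):
            wssd_depth(placements, asm, [BedInterval("c", 0, 5000)],
                       ToolConfig())


class TestCompare:
    def test_identical_and_disjoint_sets(self):
        a = {"c": [(0, 10_000)]}
        same = compare_wgac_wssd(a, [type("C", (), {
            "scaffold": "c", "start": 0, "end": 10_000})()])
        assert same == {"both_bp": 10_000, "wgac_only_bp": 0,
                        "wssd_only_bp": 0}
        disjoint = compare_wgac_wssd(a, [type("C", (), {
            "scaffold": "c", "start": 20_000, "end": 30_000})()])
        assert disjoint["both_bp"] == 0

    def test_stricter_threshold_subsetting(self):
        from asmrecon.segdup import DuplicationCall

        calls = [DuplicationCall("c", 0, 12_000, "WGAC", 0.95,
                                 ("c", 50_000, 62_000)),
                 DuplicationCall("c", 100_000, 102_000, "WGAC", 0.99,
                                 ("c", 150_000, 152_000))]
        nr = wgac_calls_at(calls, 10_000, 0.94)
        assert nr == {"c": [(0, 12_000)]}
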