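"""Gap flank extraction, verdict classification, and patching."""

import pytest

from asmrecon.core import AlignmentRecord, GapRecord, gap_census
from asmrecon.gappatch import (AMBIGUOUS, DISCORDANT, PATCHABLE,
                               SPANS_GAP, UNMAPPED, FlankPair, PatchOperation,
                               apply_patches, classify_flank_mapping,
                               closure_accounting, embedded_feature_bp,
                               extract_flanks)
from asmrecon.core import BedInterval
from conftest import asm_from


def _pair(gap=None, flank_len=1000, usable=True):
    gap = gap or GapRecord("s", 5000, 5100)
    return FlankPair(gap, "A" * flank_len, (gap.start - flank_len, gap.start),
                     "C" * flank_len, (gap.end, gap.end + flank_len), usable)


def _hit(target="d", ts=0, te=1000, strand="+", score=1000.0, qlen=1000):
    return AlignmentRecord("f", 0, qlen, qlen, target, ts, te, 1_000_000,
                           strand, te - ts, te - ts, score)


class TestExtractFlanks:
    def test_full_length_flanks(self):
        asm = asm_from({"s": "A" * 5000 + "N" * 100 + "C" * 5000})
        (fp,) = extract_flanks(asm, gap_census(asm), 1000)
        assert fp.left_interval == (4000, 5000)
        assert fp.right_interval == (5100, 6100)
        assert fp.usable

    def test_truncation_at_scaffold_start_flags_unusable(self):
        asm = asm_from({"s": "A" * 100 + "N" * 50 + "C" * 5000})
        (fp,) = extract_flanks(asm, gap_census(asm), 1000, min_flank_len=200)
        assert fp.left_interval == (0, 100)
        assert not fp.usable

    def test_truncation_at_neighboring_gap(self):
        asm = asm_from({"s": "A" * 2000 + "N" * 50 + "G" * 300 + "N" * 50
                        + "C" * 2000})
        fps = extract_flanks(asm, gap_census(asm), 1000, min_flank_len=200)
        assert fps[0].right_interval == (2050, 2350)   # capped at 300 bp
        assert fps[1].left_interval == (2050, 2350)    # same 300 bp region


class TestClassifyFlankMapping:
    def test_concordant_pair_is_patchable_with_fill(self):
        v = classify_flank_mapping(_pair(), [_hit(ts=10_000, te=11_000)],
                                   [_hit(ts=11_500, te=12_500)], [])
        assert (v.status, v.implied_fill_len) == (PATCHABLE, 500)
        assert v.fill_interval == ("d", 11_000, 11_500)

    def test_different_scaffolds_discordant(self):
        v = classify_flank_mapping(_pair(), [_hit(target="d1")],
                                   [_hit(target="d2")], [])
        assert v.status == DISCORDANT

    def test_negative_fill_from_overlapping_hits(self):
        v = classify_flank_mapping(_pair(), [_hit(ts=10_000, te=11_000)],
                                   [_hit(ts=10_960, te=11_960)], [])
        assert (v.status, v.implied_fill_len) == (PATCHABLE, -40)

    def test_donor_gap_inside_span(self):
        donor_gaps = [GapRecord("d", 11_200, 11_300)]
        v = classify_flank_mapping(_pair(), [_hit(ts=10_000, te=11_000)],
                                   [_hit(ts=11_500, te=12_500)], donor_gaps)
        assert v.status == SPANS_GAP

    def test_ambiguous_when_second_hit_close_in_score(self):
        lh = [_hit(ts=10_000, te=11_000, score=1000),
              _hit(ts=50_000, te=51_000, score=900)]
        v = classify_flank_mapping(_pair(), lh,
                                   [_hit(ts=11_500, te=12_500)], [])
        assert v.status == AMBIGUOUS

    def test_unusable_pair_unmapped(self):
        v = classify_flank_mapping(_pair(usable=False), [_hit()], [_hit()], [])
        assert v.status == UNMAPPED


class TestApplyPatches:
    def test_positive_fill_bookkeeping(self):
        asm = asm_from({"s": "A" * 1000 + "N" * 100 + "C" * 1000})
        patch = PatchOperation(GapRecord("s", 1000, 1100), "d", 0, 120, "+",
                               "G" * 120, 20)
        patched, report = apply_patches(asm, [patch])
        assert len(patched["s"]) == 2120
        assert len(gap_census(patched)) == 0
        assert len(report["applied"]) == 1

    def test_negative_fill_collapses_overlap(self):
        dup = "GATTACA" * 10  # 70 bp duplicated overlap
        asm = asm_from({"s": "A" * 1000 + dup + "N" * 100 + dup + "C" * 1000})
        gap = GapRecord("s", 1070, 1170)
        patch = PatchOperation(gap, "d", 0, 0, "+", "", -70 - 100)
        patched, _ = apply_patches(asm, [patch])
        assert patched["s"].sequence == "A" * 1000 + dup + "C" * 1000

    def test_zero_patches_is_identity(self, small_sim):
        _, derived, _ = small_sim
        patched, report = apply_patches(derived, [])
        assert all(a.sequence == b.sequence for a, b in zip(derived, patched))

    def test_length_conservation(self, small_sim):
        genome, derived, _ = small_sim
        from asmrecon.gappatch import build_patches

        patches, _ = build_patches(derived, genome)
        patched, report = apply_patches(derived, patches)
        for scaf in derived:
            delta = sum(p.length_delta for p in report["applied"]
                        if p.gap.scaffold == scaf.name)
            assert len(patched[scaf.name]) == len(scaf) + delta


class TestClosure:
    def test_self_comparison_spans_own_gaps(self, small_sim):
        _, derived, _ = small_sim
        summary = closure_accounting(derived, derived)
        assert summary.n_filled == 0
        assert summary.status_counts[SPANS_GAP] == summary.n_gaps

    def test_spectrum_has_negative_bin(self, small_sim):
        genome, derived, truth = small_sim
        summary = closure_accounting(derived, genome)
        neg_true = sum(1 for t in truth.gaps if t.fill_len < 0)
        row = summary.fill_length_spectrum.set_index("bin")
        assert row.loc["negative", "count"] == neg_true


class TestEmbedded:
    def test_containment_boundary(self):
        fills = [BedInterval("c", 100, 200, "fill")]
        feats = [BedInterval("c", 100, 200, "SINE"),   # exactly equal
                 BedInterval("c", 99, 150, "SINE"),    # 1 bp overhang
                 BedInterval("c", 150, 180, "LINE")]
        bp, counts = embedded_feature_bp(fills, feats)
        assert counts == {"SINE": 1, "LINE": 1}
        assert bp == 100  # union of the two embedded features
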