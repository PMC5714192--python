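"""Pileup evidence, edit calling thresholds, and integration."""

import pytest

from asmrecon.polish import (DEL, INS, SUB, EditOperation, SiteEvidence,
                             call_edits, integrate_edits, invert_edits,
                             pileup_sites)
from conftest import asm_from


def _sam(tmp_path, ref_len, records):
    p = tmp_path / "r.sam"
    lines = ["@HD\tVN:1.6\tSO:coordinate", f"@SQ\tSN:s\tLN:{ref_len}"]
    for name, pos, cigar, seq in records:
        lines.append(f"{name}\t0\ts\t{pos + 1}\t60\t{cigar}\t*\t0\t0\t{seq}\t*")
    p.write_text("\n".join(lines) + "\n")
    return p


class TestPileup:
    def test_all_matching_reads(self, tmp_path):
        asm = asm_from({"s": "ACGTACGTACGTACGTACGT" * 5})
        seq = asm["s"].sequence[10:30]
        sam = _sam(tmp_path, 100, [(f"r{i}", 10, "20M", seq)
                                   for i in range(10)])
        pile = pileup_sites(sam, asm)
        assert int(pile.depth["s"][15]) == 10
        assert int(pile.ref_count["s"][15]) == 10
        assert pile.alts["s"] == {}

    def test_two_bp_deletion_alleles(self, tmp_path):
        asm = asm_from({"s": "ACGTACGTACGTACGTACGT" * 5})
        seq = asm["s"].sequence[10:20] + asm["s"].sequence[22:32]
        sam = _sam(tmp_path, 100, [(f"r{i}", 10, "10M2D10M", seq)
                                   for i in range(10)])
        pile = pileup_sites(sam, asm)
        assert pile.alts["s"][20] == {("D", asm["s"].sequence[20:22]): 10}

    def test_sites_near_gap_are_guarded(self, tmp_path):
        asm = asm_from({"s": "A" * 50 + "N" * 20 + "C" * 50})
        sam = _sam(tmp_path, 120, [(f"r{i}", 30, "20M", "A" * 20)
                                   for i in range(5)])
        pile = pileup_sites(sam, asm)
        positions = {s.position for s in pile.sites()}
        assert positions == set(range(30, 40))  # 40..50 is the guard zone

    def test_unsorted_input_rejected(self, tmp_path):
        asm = asm_from({"s": "A" * 100})
        sam = _sam(tmp_path, 100, [("r1", 50, "10M", "A" * 10),
                                   ("r2", 10, "10M", "A" * 10)])
        with pytest.raises(ValueError, match="sorted"):
            pileup_sites(sam, asm)


def _site(ref="A", depth=10, **alleles):
    counts = {}
    for key, n in alleles.items():
        kind, payload = key.split("_", 1) if "_" in key else (key, "")
        counts[(kind, payload) if payload else (kind,)] = n
    return SiteEvidence("s", 100, ref, depth, counts)


class TestCallEdits:
    def test_strong_substitution_called(self):
        (e,) = call_edits([_site(R=1, S_C=9)])
        assert (e.type, e.ref, e.alt) == (SUB, "A", "C")

    def test_six_bp_insertion_excluded(self):
        assert call_edits([_site(R=0, I_CCCCCC=10)]) == []
        (e,) = call_edits([_site(R=0, I_CCCCC=10)])
        assert e.type == INS

    def test_low_depth_never_edited(self):
        assert call_edits([_site(depth=3, R=0, S_C=3)]) == []

    def test_heterozygous_like_site_left_alone(self):
        assert call_edits([_site(depth=20, R=10, S_C=10)]) == []

    def test_tie_breaks_toward_reference(self):
        assert call_edits([_site(depth=10, R=5, S_C=5)]) == []


class TestIntegrateEdits:
    def test_sub_plus_deletion_bookkeeping(self):
        asm = asm_from({"s": "AAAACCCCGGGGTTTT"})
        edits = [EditOperation("s", 2, SUB, "A", "G"),
                 EditOperation("s", 8, DEL, "GG", "")]
        out, report = integrate_edits(asm, edits)
        assert out["s"].sequence == "AAGACCCCGGTTTT"
        assert report["SUB"] == 1 and report["DEL"] == 1

    def test_empty_edit_list_identity(self, small_sim):
        _, derived, _ = small_sim
        out, _ = integrate_edits(derived, [])
        assert all(a.sequence == b.sequence for a, b in zip(derived, out))

    def test_roundtrip_through_inverse_edits(self):
        asm = asm_from({"s": "ACGTACGTACGTACGTACGTACGTACGT"}, name="x")
        edits = [EditOperation("s", 3, SUB, "T", "G"),
                 EditOperation("s", 10, INS, "", "AAA"),
                 EditOperation("s", 20, DEL, "ACGT", "")]
        forward, _ = integrate_edits(asm, edits)
        back, _ = integrate_edits(forward, invert_edits(edits))
        assert back["s"].sequence == asm["s"].sequence

    def test_mismatching_ref_is_error(self):
        asm = asm_from({"s": "AAAA"})
        with pytest.raises(ValueError, match="mismatch"):
            integrate_edits(asm, [EditOperation("s", 1, SUB, "C", "G")])


class TestClosedLoop:
    def test_planted_errors_reverted_without_false_edits(self):
        from asmrecon.pipeline import polish_metrics

        m = polish_metrics(seed=5, genome_len=120_000, n_subs=80,
                           n_indels=60, n_six_bp=2)
        assert m["revert_rate"] >= 0.99
        assert m["false_edits"] == 0
        assert m["oversize_indels_edited"] == 0
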