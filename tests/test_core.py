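"""Domain types, gap/contig definitions, and format round-trips."""

import re

import numpy as np
import pytest

from asmrecon.core import (AlignmentRecord, Assembly, agp_gaps,
                           assembly_to_agp, cigar_matches, gap_census,
                           intersect_bp, merge_intervals, read_agp,
                           read_alignments, read_fasta, scan_gaps,
                           subtract_intervals, union_bp, write_agp,
                           write_fasta)
from conftest import asm_from


class TestFasta:
    def test_basic_parse_and_case_folding(self, tmp_path):
        p = tmp_path / "a.fa"
        p.write_text(">s1\nACGTN\n>s2\nacgt\nacgt\n")
        asm = read_fasta(p)
        assert [s.name for s in asm] == ["s1", "s2"]
        assert asm["s1"].sequence == "ACGTN"
        assert asm["s2"].sequence == "ACGTACGT"

    def test_ambiguity_codes_become_n(self, tmp_path):
        p = tmp_path / "a.fa"
        p.write_text(">s1\nACRT\n")
        assert read_fasta(p)["s1"].sequence == "ACNT"

    def test_header_token_before_whitespace(self, tmp_path):
        p = tmp_path / "a.fa"
        p.write_text(">scaf1 some description\nACGT\n")
        assert read_fasta(p)["scaf1"].sequence == "ACGT"

    def test_duplicate_name_is_hard_error(self, tmp_path):
        p = tmp_path / "a.fa"
        p.write_text(">s1\nACGT\n>s1\nTTTT\n")
        with pytest.raises(ValueError, match="duplicate"):
            read_fasta(p)

    def test_roundtrip_and_line_width(self, tmp_path, small_sim):
        _, derived, _ = small_sim
        p = write_fasta(derived, tmp_path / "d.fa", line_width=60)
        assert max(len(l) for l in p.read_text().splitlines()) <= 61
        back = read_fasta(p)
        assert all(a.name == b.name and a.sequence == b.sequence
                   for a, b in zip(derived, back))

    def test_empty_assembly_writes_empty_file(self, tmp_path):
        p = write_fasta(Assembly("e", []), tmp_path / "e.fa")
        assert p.read_text() == ""


class TestGapCensus:
    @pytest.mark.parametrize("n_run,expected", [(9, 0), (10, 1), (15, 1)])
    def test_minimum_run_length_boundary(self, n_run, expected):
        seq = "ACGT" + "N" * n_run + "ACGT"
        assert len(scan_gaps("s", seq, 10)) == expected

    def test_short_runs_stay_contig_internal(self):
        gaps = scan_gaps("s", "ACGT" + "N" * 12 + "AC" + "N" * 3 + "GT", 10)
        assert [(g.start, g.end) for g in gaps] == [(4, 16)]

    def test_matches_regex_oracle_on_random_sequences(self):
        rng = np.random.default_rng(7)
        for _ in range(300):
            n = int(rng.integers(20, 400))
            seq = "".join(rng.choice(list("ACGTNN"), size=n))
            got = [(g.start, g.end) for g in scan_gaps("s", seq, 10)]
            want = [(m.start(), m.end())
                    for m in re.finditer(r"N{10,}", seq)]
            assert got == want

    def test_partition_property(self, small_sim):
        _, derived, _ = small_sim
        for scaf in derived:
            gaps = scaf.gaps(10)
            contigs = scaf.contigs(10)
            total = sum(g.length for g in gaps) + sum(e - s
                                                      for s, e in contigs)
            assert total == len(scaf)

    def test_census_sorted_by_scaffold_then_start(self, small_sim):
        _, derived, _ = small_sim
        gaps = gap_census(derived)
        order = [s.name for s in derived]
        keys = [(order.index(g.scaffold), g.start) for g in gaps]
        assert keys == sorted(keys)


class TestAgp:
    def test_contig_gap_structure(self):
        asm = asm_from({"s": "A" * 50 + "N" * 100 + "C" * 30})
        rows = assembly_to_agp(asm)
        assert [(r.component_type, r.object_beg, r.object_end)
                for r in rows] == [("W", 1, 50), ("N", 51, 150),
                                   ("W", 151, 180)]

    def test_roundtrip(self, tmp_path, small_sim):
        _, derived, _ = small_sim
        p = write_agp(derived, tmp_path / "d.agp")
        assert read_agp(p) == assembly_to_agp(derived)

    def test_gap_rows_agree_with_census(self, tmp_path, small_sim):
        _, derived, _ = small_sim
        p = write_agp(derived, tmp_path / "d.agp")
        got = [(g.scaffold, g.start, g.end) for g in agp_gaps(read_agp(p))]
        want = [(g.scaffold, g.start, g.end) for g in gap_census(derived)]
        assert got == want

    def test_overlapping_coordinates_error_names_line(self, tmp_path):
        p = tmp_path / "bad.agp"
        p.write_text("s\t1\t50\t1\tW\tc1\t1\t50\t+\n"
                     "s\t40\t80\t2\tW\tc2\t1\t41\t+\n")
        with pytest.raises(ValueError, match=":2"):
            read_agp(p)


class TestAlignmentRecords:
    def test_paf_identity_from_matches_and_columns(self, tmp_path):
        p = tmp_path / "a.paf"
        p.write_text("q\t1000\t0\t1000\t+\tt\t5000\t100\t1100\t950\t1000\t60\n")
        (rec,) = read_alignments(p, "PAF")
        assert rec.identity == pytest.approx(0.95)

    def test_reversed_interval_rejected(self):
        with pytest.raises(ValueError):
            AlignmentRecord("q", 10, 5, 20, "t", 0, 10, 100, "+", 5, 5)

    def test_sam_cigar_and_nm_arithmetic(self):
        # 10M2D10M with NM=2: both mismatch-free; 22 aligned columns
        assert cigar_matches("10M2D10M", 2) == (20, 22)
        assert cigar_matches("10=2X10=", 2) == (20, 22)

    def test_sam_file_parsing(self, tmp_path):
        p = tmp_path / "a.sam"
        p.write_text("@HD\tVN:1.6\n@SQ\tSN:t\tLN:100\n"
                     "r1\t0\tt\t11\t60\t10M2D10M\t*\t0\t0\t"
                     + "A" * 20 + "\t*\tNM:i:2\n")
        (rec,) = read_alignments(p, "SAM")
        assert (rec.matches, rec.aligned_columns) == (20, 22)
        assert (rec.target_start, rec.target_end) == (10, 32)


class TestIntervalAlgebra:
    def test_union_and_merge(self):
        assert union_bp([(0, 1000), (500, 1500)]) == 1500
        assert merge_intervals([(5, 8), (0, 3), (2, 6)]) == [(0, 8)]

    def test_intersect_and_subtract(self):
        assert intersect_bp([(0, 100)], [(50, 150)]) == 50
        assert subtract_intervals([(0, 100)], [(20, 30), (90, 200)]) \
            == [(0, 20), (30, 90)]
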