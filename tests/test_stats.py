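"""Contiguity statistics, annotation deltas, and the permutation test."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from asmrecon.core import BedInterval, ToolConfig
from asmrecon.stats import (annotation_delta, assembly_stats,
                            identity_summary, non_gap_universe, nxx,
                            permutation_enrichment)
from conftest import asm_from


def nxx_oracle(lengths, x):
    """Brute-force cumulative-sum reference implementation."""
    total = sum(lengths)
    cum = 0
    for L in sorted(lengths, reverse=True):
        cum += L
        if cum >= x * total:
            return L
    raise AssertionError


class TestNxx:
    def test_examples(self):
        assert nxx([100], 0.5) == 100
        assert nxx([8, 4, 4, 2], 0.5) == 4

    def test_empty_is_error(self):
        with pytest.raises(ValueError):
            nxx([], 0.5)

    @given(st.lists(st.integers(1, 10_000), min_size=1, max_size=60),
           st.sampled_from([0.1, 0.5, 0.9, 1.0]))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_agrees_with_bruteforce_oracle(self, lengths, x):
        assert nxx(lengths, x) == nxx_oracle(lengths, x)

    @given(st.lists(st.integers(1, 10_000), min_size=1, max_size=40))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_order_invariant_and_monotone(self, lengths):
        n50 = nxx(lengths, 0.5)
        assert nxx(list(reversed(sorted(lengths))), 0.5) == n50
        assert nxx(lengths + [n50 + 1], 0.5) >= n50


class TestAssemblyStats:
    def test_single_gapless_scaffold(self):
        st_ = assembly_stats(asm_from({"s": "ACGT" * 100}))
        assert (st_.n_contigs, st_.n_gaps) == (1, 0)
        assert st_.total_len == st_.total_len_no_n == 400

    def test_simulator_ground_truth_counts(self, small_sim):
        _, derived, truth = small_sim
        st_ = assembly_stats(derived)
        assert st_.n_gaps == len(truth.gaps) == 12
        assert st_.n_contigs == st_.n_scaffolds + st_.n_gaps
        n_bases_in_gaps = sum(t.end - t.start for t in truth.gaps)
        assert st_.total_len - st_.total_len_no_n == n_bases_in_gaps

    def test_short_n_runs_excluded_from_no_n_length(self):
        st_ = assembly_stats(asm_from({"s": "ACGT" + "N" * 5 + "ACGT"}))
        assert st_.n_gaps == 0            # below the 10-N threshold
        assert st_.total_len_no_n == 8    # but still not sequence


class TestAnnotationDelta:
    def test_percent_increase_per_family(self):
        old = [BedInterval("c", 0, 1000, "SINE")]
        new = [BedInterval("c", 0, 1279, "SINE")]
        df = annotation_delta(old, new)
        assert df.loc["SINE", "pct_increase"] == pytest.approx(27.9)

    def test_identical_sets_zero_delta(self):
        ivs = [BedInterval("c", 5, 50, "LINE"), BedInterval("c", 60, 90, "LINE")]
        df = annotation_delta(ivs, list(ivs))
        assert (df["delta_bp"] == 0).all()

    def test_overlaps_within_family_counted_once(self):
        new = [BedInterval("c", 0, 100, "LTR"), BedInterval("c", 50, 150, "LTR")]
        df = annotation_delta([], new)
        assert df.loc["LTR", "new_bp"] == 150


class TestIdentitySummary:
    def test_column_weighted_vs_record_mean(self):
        from asmrecon.core import AlignmentRecord

        def rec(matches, cols):
            return AlignmentRecord("q", 0, cols, cols, "t", 0, cols,
                                   10_000, "+", matches, cols)

        alns = [rec(100, 100), rec(80, 100)]
        assert identity_summary(alns) == pytest.approx(0.90)
        assert identity_summary(alns, "record-mean") == pytest.approx(0.90)
        skew = [rec(1000, 1000), rec(80, 100)]
        assert identity_summary(skew) == pytest.approx(1080 / 1100)
        with pytest.raises(ValueError):
            identity_summary([])


class TestPermutationEnrichment:
    def test_features_covering_universe_give_p_one(self):
        universe = [BedInterval("c", 0, 10_000)]
        feats = [BedInterval("c", 0, 10_000, "f")]
        query = [BedInterval("c", i * 100, i * 100 + 50, "q")
                 for i in range(10)]
        res = permutation_enrichment(query, feats, universe,
                                     ToolConfig(perm_reps=99, rng_seed=1))
        assert res.observed_overlap_fraction == 1.0
        assert res.empirical_p == 1.0

    def test_planted_containment_reaches_minimum_p(self):
        universe = [BedInterval("c", 0, 100_000)]
        feats = [BedInterval("c", s, s + 1000, "f")
                 for s in range(0, 100_000, 10_000)]
        query = [BedInterval("c", s + 100, s + 300, "q")
                 for s in range(0, 100_000, 10_000)]
        res = permutation_enrichment(query, feats, universe,
                                     ToolConfig(perm_reps=999, rng_seed=1))
        assert res.empirical_p == pytest.approx(1 / 1000)

    def test_oversized_query_interval_is_error(self):
        universe = [BedInterval("c", 0, 100)]
        query = [BedInterval("c", 0, 100, "q")]
        with pytest.raises(ValueError, match="longer"):
            permutation_enrichment(query, [], [BedInterval("c", 0, 50)],
                                   ToolConfig(perm_reps=9))
        # fits exactly -> fine
        permutation_enrichment(query, [], universe, ToolConfig(perm_reps=9))

    def test_non_gap_universe_excludes_gaps(self, small_sim):
        _, derived, truth = small_sim
        universe = non_gap_universe(derived)
        gap_spans = {(t.scaffold, t.start, t.end) for t in truth.gaps}
        for iv in universe:
            for scaf, s, e in gap_spans:
                assert not (iv.chrom == scaf and iv.start < e and iv.end > s)
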