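"""Insert-size model, pair classification, break calling and application."""

import numpy as np
import pytest

from asmrecon.breakfix import (AMBIGUOUS, BAD_DISTANCE, CONCORDANT, PARTIAL,
                               WRONG_ORIENTATION, WRONG_SCAFFOLD, BreakCall,
                               EndMapping, EndPair, InsertModel, apply_breaks,
                               call_breaks, classify_pairs, fit_insert_model)
from conftest import asm_from


def _pair(pid, scaf_a, pos_a, strand_a, scaf_b, pos_b, strand_b,
          end_len=600, unique=True):
    def end(s, p, st):
        return None if s is None else EndMapping(s, p, p + end_len, st)
    return EndPair(pid, end(scaf_a, pos_a, strand_a),
                   end(scaf_b, pos_b, strand_b), unique)


MODEL = InsertModel(40_000, 4_000, 3.0)


class TestInsertModel:
    def test_recovers_normal_parameters(self):
        rng = np.random.default_rng(5)
        pairs = []
        for i, ins in enumerate(rng.normal(40_000, 4_000, size=2000)):
            pairs.append(_pair(f"p{i}", "s", 100_000, "+",
                               "s", 100_000 + int(ins) - 600, "-"))
        m = fit_insert_model(pairs)
        assert m.mean == pytest.approx(40_000, abs=300)
        assert m.sd == pytest.approx(4_000, abs=300)

    def test_degenerate_inserts_hit_sd_floor(self):
        pairs = [_pair(f"p{i}", "s", 0, "+", "s", 39_400, "-")
                 for i in range(60)]
        assert fit_insert_model(pairs).sd == 1.0

    def test_robust_to_chimera_contamination(self):
        rng = np.random.default_rng(6)
        pairs = []
        for i, ins in enumerate(rng.normal(40_000, 4_000, size=950)):
            pairs.append(_pair(f"p{i}", "s", 10_000, "+",
                               "s", 10_000 + int(ins) - 600, "-"))
        for i, ins in enumerate(rng.uniform(100_000, 900_000, size=50)):
            pairs.append(_pair(f"c{i}", "s", 10_000, "+",
                               "s", 10_000 + int(ins) - 600, "-"))
        assert fit_insert_model(pairs).mean == pytest.approx(40_000, rel=0.02)

    def test_too_few_pairs_is_error(self):
        with pytest.raises(ValueError, match="explicit"):
            fit_insert_model([_pair("p", "s", 0, "+", "s", 39_000, "-")])


class TestClassifyPairs:
    @pytest.mark.parametrize("pair,verdict", [
        (_pair("a", "s", 0, "+", "s", 40_400, "-"), CONCORDANT),
        (_pair("b", "s", 0, "+", "s", 20_000, "+"), WRONG_ORIENTATION),
        (_pair("c", "s", 0, "+", "s", 89_400, "-"), BAD_DISTANCE),
        (_pair("d", "s", 0, "-", "s", 40_400, "+"), WRONG_ORIENTATION),
        (_pair("e", "s1", 0, "+", "s2", 40_000, "-"), WRONG_SCAFFOLD),
        (_pair("f", "s", 0, "+", None, None, None), PARTIAL),
        (_pair("g", "s", 0, "+", "s", 40_400, "-", unique=False), AMBIGUOUS),
    ], ids=["innie-in-range", "tandem", "too-far", "outie",
            "cross-scaffold", "one-end-missing", "non-unique"])
    def test_rule_table(self, pair, verdict):
        (obs,) = classify_pairs([pair], MODEL)
        assert obs.verdict == verdict

    def test_distance_boundary_three_sds(self):
        # 52 kbp = mean + 3 sd exactly -> still concordant; 1 bp more is not
        at = _pair("a", "s", 0, "+", "s", 52_000 - 600, "-")
        beyond = _pair("b", "s", 0, "+", "s", 52_001 - 600, "-")
        assert classify_pairs([at], MODEL)[0].verdict == CONCORDANT
        assert classify_pairs([beyond], MODEL)[0].verdict == BAD_DISTANCE


class TestCallBreaks:
    def test_below_cluster_threshold_no_call(self):
        asm = asm_from({"s": "ACGT" * 300_000})
        pairs = [_pair(f"p{i}", "s", 100_000, "+", "s", 200_000, "+")
                 for i in range(2)]
        obs = classify_pairs(pairs, MODEL)
        assert call_breaks(obs, asm) == []

    def test_planted_junctions_recovered(self):
        from asmrecon.pipeline import breakfix_metrics

        m = breakfix_metrics(seed=3, genome_len=2_000_000, inversions=2)
        assert m["recall"] == 1.0
        assert m["false_positives"] == 0

    def test_correct_assembly_produces_no_calls(self):
        from asmrecon.pipeline import breakfix_null_metrics

        m = breakfix_null_metrics(seed=3)
        assert m["n_calls"] == 0
        assert m["concordant_fraction"] > 0.98


class TestApplyBreaks:
    def test_break_at_gap_removes_ns_conserves_bases(self):
        asm = asm_from({"s": "A" * 500_000 + "N" * 100 + "C" * 500_000})
        call = BreakCall("s", 499_000, 501_000, 5, 0, 500_050, True)
        broken = apply_breaks(asm, [call])
        assert [s.name for s in broken] == ["s_1", "s_2"]
        non_n = sum(len(s) - s.sequence.count("N") for s in broken)
        assert non_n == 1_000_000

    def test_break_between_bases_loses_nothing(self):
        asm = asm_from({"s": "ACGT" * 1000})
        call = BreakCall("s", 1000, 3000, 5, 0, 2000, False)
        broken = apply_breaks(asm, [call])
        assert "".join(s.sequence for s in broken) == asm["s"].sequence

    def test_zero_calls_identity(self, small_sim):
        _, derived, _ = small_sim
        broken = apply_breaks(derived, [])
        assert [s.name for s in broken] == [s.name for s in derived]
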