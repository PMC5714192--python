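"""Synthetic-data generator: determinism, planted structure, coverage."""

import numpy as np
import pytest

from asmrecon.core import gap_census
from asmrecon.simulate import (DupSpec, ErrorPlan, GapPlan, SimConfig,
                               derive_assembly, make_genome,
                               simulate_end_pairs, simulate_reads)


def test_same_seed_gives_identical_output():
    cfg = SimConfig(genome_len=150_000, seed=9,
                    gaps=GapPlan(count=8, neg_frac=0.3),
                    errors=ErrorPlan(substitutions=20, indels=10))
    out = []
    for _ in range(2):
        genome, feats = make_genome(cfg)
        derived, truth = derive_assembly(genome, cfg, feats)
        out.append((tuple(s.sequence for s in genome),
                    tuple(s.sequence for s in derived),
                    tuple((t.scaffold, t.start, t.end, t.fill_len)
                          for t in truth.gaps)))
    assert out[0] == out[1]


def test_planted_gap_count_and_coordinates(small_sim):
    _, derived, truth = small_sim
    census = gap_census(derived)
    assert len(census) == len(truth.gaps) == 12
    assert [(g.scaffold, g.start, g.end) for g in census] \
        == [(t.scaffold, t.start, t.end) for t in truth.gaps]


def test_no_defects_means_identity():
    cfg = SimConfig(genome_len=80_000, seed=4)
    genome, feats = make_genome(cfg)
    derived, truth = derive_assembly(genome, cfg, feats)
    assert all(a.sequence == b.sequence for a, b in zip(genome, derived))
    assert not truth.gaps and not truth.errors and not truth.junctions


def test_positive_gap_replaces_true_fill_sequence(small_sim):
    genome, derived, truth = small_sim
    for t, spec in zip(sorted(truth.gaps, key=lambda t: (t.scaffold, t.start)),
                       sorted(truth.gap_specs,
                              key=lambda s: (s.scaffold, s.pos))):
        assert t.fill_len == spec.fill_len
        if spec.fill_len > 0:
            assert t.fill_seq == genome[spec.scaffold].sequence[
                spec.pos:spec.pos + spec.fill_len]
        else:  # overlap duplicated on both sides of the N-run
            o = -spec.fill_len
            dup = genome[spec.scaffold].sequence[spec.pos:spec.pos + o]
            assert derived[t.scaffold].sequence[t.end:t.end + o] == dup
            assert derived[t.scaffold].sequence[t.start - o:t.start] == dup


def test_end_pair_count_follows_physical_coverage():
    genome, _ = make_genome(SimConfig(genome_len=2_000_000, seed=2))
    pairs = simulate_end_pairs(genome, None, insert_mean=40_000,
                               insert_sd=4_000, phys_coverage=6.0, seed=1)
    assert len(pairs) == pytest.approx(6 * 2_000_000 / 40_000, abs=1)


def test_read_count_and_exactness_without_errors():
    genome, _ = make_genome(SimConfig(genome_len=100_000, seed=2))
    reads = simulate_reads(genome, None, target=genome, coverage=5,
                           read_len=100, seed=3)
    assert len(reads) == 5000
    seq = genome["chr1"].sequence
    for r in reads[:200]:
        assert seq[r.start:r.end] == r.seq
        assert r.identity == 1.0


def test_collapsed_duplication_doubles_local_depth():
    cfg = SimConfig(genome_len=300_000, seed=6,
                    duplications=[DupSpec(15_000, 0.99, collapsed=True)],
                    feature_margin=20_000)
    genome, feats = make_genome(cfg)
    derived, truth = derive_assembly(genome, cfg, feats)
    dup = feats.duplications[0]
    assert len(derived["chr1"]) == len(genome["chr1"]) - 15_000
    reads = simulate_reads(genome, truth, target=derived, coverage=8,
                           read_len=100, seed=7)
    cov = np.zeros(len(derived["chr1"]) + 1)
    for r in reads:
        cov[r.start] += 1
        cov[r.end] -= 1
    cov = np.cumsum(cov)[:-1]
    src = truth.map_genome("chr1", dup.src[0] + 7500)
    inside = cov[src[1] - 2000:src[1] + 2000].mean()
    outside = np.median(cov)
    assert inside / outside == pytest.approx(2.0, rel=0.15)
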