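"""Built-in seeded aligner: seeding, extension, strand, uniqueness."""

import numpy as np
import pytest

from asmrecon.align import KmerIndex, is_unique, map_query
from asmrecon.core import revcomp
from asmrecon.simulate import SimConfig, make_genome
from conftest import asm_from


@pytest.fixture(scope="module")
def random_genome():
    genome, _ = make_genome(SimConfig(genome_len=200_000, seed=11))
    return genome


def test_exact_substring_maps_uniquely(random_genome):
    idx = KmerIndex(random_genome)
    q = random_genome["chr1"].sequence[50_000:51_000]
    hits = map_query(idx, q, "q")
    assert hits and hits[0].target_start == 50_000
    assert hits[0].identity == 1.0
    assert is_unique(hits)


def test_reverse_complement_query_found_on_minus_strand(random_genome):
    idx = KmerIndex(random_genome)
    q = revcomp(random_genome["chr1"].sequence[80_000:81_000])
    hits = map_query(idx, q, "q")
    assert hits[0].strand == "-"
    assert (hits[0].target_start, hits[0].target_end) == (80_000, 81_000)


def test_diverged_query_still_maps_with_reduced_identity(random_genome):
    rng = np.random.default_rng(3)
    seq = list(random_genome["chr1"].sequence[120_000:121_000])
    for i in rng.choice(1000, size=50, replace=False):
        seq[i] = "ACGT"["ACGT".index(seq[i]) - 1]
    hits = map_query(idx := KmerIndex(random_genome), "".join(seq), "q")
    assert hits[0].target_start == pytest.approx(120_000, abs=5)
    assert 0.93 <= hits[0].identity <= 0.97


def test_two_copy_segment_is_not_unique():
    genome, _ = make_genome(SimConfig(genome_len=100_000, seed=12))
    seq = genome["chr1"].sequence
    unit = seq[40_000:41_200]  # planted again at a second locus
    asm = asm_from({"chr1": seq[:20_000] + unit + seq[20_000:]})
    hits = map_query(KmerIndex(asm), unit, "q")
    assert len(hits) >= 2
    assert not is_unique(hits, margin=0.2)
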