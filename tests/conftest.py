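import pytest

from asmrecon.core import Assembly, Scaffold
from asmrecon.simulate import GapPlan, SimConfig, derive_assembly, make_genome


def asm_from(seqs: dict[str, str], name: str = "test") -> Assembly:
    return Assembly(name, [Scaffold(n, s) for n, s in seqs.items()])


@pytest.fixture(scope="session")
def small_sim():
    """A 300 kbp genome with 12 planted gaps and its gapped derivative,
    shared by tests that only read from it."""
    cfg = SimConfig(genome_len=300_000, seed=42,
                    gaps=GapPlan(count=12, neg_frac=0.25))
    genome, feats = make_genome(cfg)
    derived, truth = derive_assembly(genome, cfg, feats)
    return genome, derived, truth
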