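import numpy as np
import pytest

import te4c
from te4c import ConsensusSequence, Genome, SimConfig


def random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))


@pytest.fixture(scope="session")
def consensus() -> ConsensusSequence:
    """A 2 kb ERV-like consensus with one qualifying bait candidate.

    Primary (GATC) sites at 100 and 500 (spacing 400 >= 300), a secondary
    (GTAC) site at 260 (160 >= 150 from the upstream primary site), and no
    stray sites elsewhere.
    """
    rng = np.random.default_rng(0)
    seq = random_dna(rng, 2000)
    seq = seq.replace("GATC", "AAAA").replace("GTAC", "CCCC")
    seq = seq[:100] + "GATC" + seq[104:260] + "GTAC" + seq[264:500] + "GATC" + seq[504:]
    return ConsensusSequence("ERVsim", seq)


@pytest.fixture(scope="session")
def primer_pair(consensus):
    cands = te4c.enumerate_bait_candidates(consensus, te4c.DPNII, te4c.CSP6I)
    assert len(cands) == 1
    return te4c.design_primer_pair(cands[0], consensus, te4c.DPNII)


@pytest.fixture(scope="session")
def primer_segments(primer_pair):
    pp = primer_pair
    return [
        (pp.reading_pos, pp.reading_pos + len(pp.reading_primer)),
        (pp.second_pos, pp.second_pos + len(pp.second_primer)),
    ]


@pytest.fixture(scope="session")
def small_genome() -> Genome:
    rng = np.random.default_rng(42)
    return Genome({"chr1": random_dna(rng, 20_000), "chr2": random_dna(rng, 15_000)})
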