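import numpy as np
import pytest

from dtrflp import synth
from dtrflp.seqio import Read


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


@pytest.fixture
def random_seq(rng):
    def make(length: int, alphabet: str = "ACGT") -> str:
        return "".join(rng.choice(list(alphabet), size=length))

    return make


@pytest.fixture(scope="session")
def small_community():
    """An error-free five-taxon community with pinned HaeIII sites."""
    records, truth = synth.make_reference_db(
        5, site_positions=[80, 120, 160, 200, 240], seed=101
    )
    spec = synth.CommunitySpec(
        taxa=[(r, 0.2) for r in records],
        read_count=100,
        substitution_rate=0.0,
        homopolymer_indel_rate=0.0,
        seed=102,
    )
    reads, read_truth = synth.simulate_reads(spec)
    return records, reads, read_truth


def make_read(seq: str, rid: str = "r1", quality: int | None = 40) -> Read:
    quals = None if quality is None else [quality] * len(seq)
    return Read(rid, seq, quals)
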