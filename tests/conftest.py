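import numpy as np
import pytest

from bwtdp.index_core import build_index

BASES = np.array(list("ACGT"))


def random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(BASES[rng.integers(0, 4, size=length)])


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def genome_50k():
    g = random_dna(np.random.default_rng(101), 50_000)
    return g


@pytest.fixture(scope="session")
def index_50k(genome_50k):
    return build_index({"chr1": genome_50k})
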