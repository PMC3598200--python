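import numpy as np
import pytest

from hiddenstops.genetic_codes import ALL_CODONS, get_genetic_code
from hiddenstops.codon_metrics import CodonUsageTable
from hiddenstops.sequence_io import coding_sequence


@pytest.fixture(scope="session")
def std_code():
    """Standard genetic code (NCBI table 1)."""
    return get_genetic_code(1)


@pytest.fixture(scope="session")
def mito_code():
    """Vertebrate mitochondrial code (NCBI table 2): AGA/AGG are stops."""
    return get_genetic_code(2)


@pytest.fixture(scope="session")
def uniform_usage():
    """Usage table with all 64 codons equally frequent."""
    return CodonUsageTable(counts={c: 1 for c in ALL_CODONS}, source="uniform")


@pytest.fixture()
def rng():
    return np.random.default_rng(20260928)


@pytest.fixture()
def example_cds():
    """The worked 4-codon example: one +1 hidden stop (TAA at nt 4)."""
    return coding_sequence("ATGTTAAAATGA", "example")


def random_dna(rng, length):
    return "".join(rng.choice(list("ACGT"), size=length))
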