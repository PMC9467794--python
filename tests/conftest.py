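import numpy as np
import pytest

from cubkit.codonio import CANONICAL_CODON_ORDER, STANDARD_CODE, CodonCountTable


@pytest.fixture(scope="session")
def code():
    return STANDARD_CODE


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


def random_count_table(rng, gene_id="g", max_count=50, p_zero=0.2):
    """A random 64-codon count table with some zero cells."""
    counts = {}
    for codon in CANONICAL_CODON_ORDER:
        if rng.random() < p_zero:
            counts[codon] = 0
        else:
            counts[codon] = int(rng.integers(0, max_count + 1))
    return CodonCountTable(gene_id, counts)


@pytest.fixture
def random_table_factory(rng):
    def make(gene_id="g", max_count=50, p_zero=0.2):
        return random_count_table(rng, gene_id, max_count, p_zero)

    return make


def write_fasta(path, entries, width=60):
    """entries: list of (header, sequence)."""
    with open(path, "w") as fh:
        for header, seq in entries:
            fh.write(f">{header}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")
    return path
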