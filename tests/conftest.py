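import numpy as np
import pytest

from minicount import (
    ReadRecord,
    SimSpec,
    build_ordering,
    simulate_genome,
    simulate_reads,
)

BASES = "ACGT"


def random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(BASES[i] for i in rng.integers(0, 4, size=length))


def random_kmer_words(rng: np.random.Generator, n: int, k: int) -> np.ndarray:
    """Random packed k-mer keys as an (n, W) uint64 word array."""
    from minicount.packing import codes_to_words

    codes = rng.integers(0, 4, size=(n, k)).astype(np.uint8)
    return codes_to_words(codes)


@pytest.fixture(scope="session")
def lex3():
    return build_ordering("lex", 3)


@pytest.fixture(scope="session")
def default_fixture(tmp_path_factory):
    """The seeded desk-scale read set: 100 kb genome, 100 bp reads,
    coverage 10, 1% substitution errors, 0.1% N-masking."""
    spec = SimSpec(seed=0)
    genome = simulate_genome(spec)
    path = tmp_path_factory.mktemp("fixture") / "reads.fastq"
    simulate_reads(genome, spec, path)
    return path, spec


@pytest.fixture(scope="session")
def small_reads():
    """A small in-memory read set (error-free, with a few Ns) for unit tests."""
    rng = np.random.default_rng(11)
    genome = random_dna(rng, 2000)
    reads = []
    for i in range(60):
        start = int(rng.integers(0, len(genome) - 100 + 1))
        seq = genome[start : start + 100]
        if rng.random() < 0.2:  # sprinkle an ambiguous base
            j = int(rng.integers(0, 100))
            seq = seq[:j] + "N" + seq[j + 1 :]
        reads.append(ReadRecord(id=f"r{i}", seq=seq))
    return reads
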