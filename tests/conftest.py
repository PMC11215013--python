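import numpy as np
import pytest

from mpchg.seq_io import PairedDataset, SequencePair


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def random_pairs(rng, n_pairs, length=60, prefix="p"):
    """Uniform-random paired dataset for unit tests."""
    bases = np.array(list("ACGT"))
    pairs = []
    for i in range(n_pairs):
        sa = "".join(rng.choice(bases, size=length))
        sb = "".join(rng.choice(bases, size=length))
        pairs.append(SequencePair(f"{prefix}{i}", sa, sb))
    return PairedDataset(pairs)


@pytest.fixture
def small_dataset(rng):
    return random_pairs(rng, 20, length=80)


def write_fasta(path, records):
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n{seq}\n")
    return path
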