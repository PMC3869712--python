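import numpy as np
import pytest

from barcodekit.seqio import Alignment, BarcodeRecord

BASES = "ACGT"


def make_alignment(entries):
    """entries: list of (seq_id, species, population, sequence)."""
    return Alignment.from_records(
        BarcodeRecord(seq_id=i, species=sp, population=pop, sequence=seq)
        for i, sp, pop, seq in entries
    )


def random_sequence(rng, length):
    return "".join(rng.choice(list(BASES), size=length))


def mutate(rng, seq, positions, transition=True):
    """Substitute at given positions: transition partner or a transversion."""
    ts = {"A": "G", "G": "A", "C": "T", "T": "C"}
    tv = {"A": "C", "C": "A", "G": "T", "T": "G"}
    out = list(seq)
    for p in positions:
        out[p] = (ts if transition else tv)[out[p]]
    return "".join(out)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def two_species_library(rng):
    """Two well-separated species, 5 sequences each, length 300."""
    L = 300
    anc_a = random_sequence(rng, L)
    anc_b = mutate(rng, anc_a, rng.choice(L, size=30, replace=False))
    entries = []
    for k in range(5):
        pos = rng.choice(L, size=2, replace=False)
        entries.append((f"a{k}", "Alpha one", "p1", mutate(rng, anc_a, pos)))
    for k in range(5):
        pos = rng.choice(L, size=2, replace=False)
        entries.append((f"b{k}", "Beta two", "p1", mutate(rng, anc_b, pos)))
    return make_alignment(entries)
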