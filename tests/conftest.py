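import numpy as np
import pytest

from matemerge import MatePair, ReadRecord, reverse_complement


def make_read(bases: str, quals=None, read_id: str = "r", mate: int = 1) -> ReadRecord:
    if quals is None:
        quals = np.full(len(bases), 30, dtype=np.int16)
    elif isinstance(quals, int):
        quals = np.full(len(bases), quals, dtype=np.int16)
    return ReadRecord(read_id, bases, np.asarray(quals, dtype=np.int16), mate=mate)


def pair_from_insert(
    insert: str,
    read_len: int,
    adapter: str = "AGATCGGAAGAGCGGTTCAGCAGGAATGCCGAGA",
    quals=30,
    read_id: str = "p",
) -> MatePair:
    """Build an error-free mate pair reading both ends of an insert."""
    rc = reverse_complement(make_read(insert)).bases
    fwd = (insert + adapter * 10)[:read_len]
    rev = (rc + adapter * 10)[:read_len]
    return MatePair(
        fwd=make_read(fwd, quals, read_id, mate=1),
        rev=make_read(rev, quals, read_id, mate=2),
    )


def random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))


@pytest.fixture(scope="session")
def small_library():
    """2,000-pair simulated library with default profiles, shared across tests."""
    from matemerge import SimProfile, simulate_pairs

    profile = SimProfile(n_pairs=2000, seed=42)
    pairs, truths, ref = simulate_pairs(profile)
    return profile, pairs, truths, ref
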