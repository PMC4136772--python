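import numpy as np
import pytest

from lrdalign import Sequence

BASES = "ACGT"


def random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(BASES[i] for i in rng.integers(0, 4, size=length))


def mutated_copy(rng: np.random.Generator, bases: str, rate: float) -> str:
    out = list(bases)
    for j in np.flatnonzero(rng.random(len(out)) < rate):
        out[j] = BASES[(BASES.index(out[j]) + 1 + rng.integers(3)) % 4]
    return "".join(out)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture
def toy_reference() -> Sequence:
    return Sequence("ref", "TTTTACGTACGTTTT")
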