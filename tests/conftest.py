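import numpy as np
import pytest

from orfwalk.sequence import Read


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_read(sequence: str, quality: int = 40, read_id: str = "r", mate: int = 0):
    return Read(id=read_id, sequence=sequence,
                qualities=(quality,) * len(sequence), mate=mate)


def random_dna(rng, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))


@pytest.fixture(scope="session")
def table1():
    from orfwalk.ratio_stats import load_table1

    return load_table1()
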