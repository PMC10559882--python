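import numpy as np
import pytest

from btsforecast.sequence_io import CANONICAL, DnaSequence


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_dna(rng: np.random.Generator, n: int, id: str = "r") -> DnaSequence:
    return DnaSequence(id=id, bases="".join(CANONICAL[i] for i in rng.integers(0, 4, n)))


@pytest.fixture
def small_fasta(tmp_path):
    p = tmp_path / "in.fa"
    p.write_text(">x\nACGT\n>y desc\nacgtACGT\n")
    return p
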