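import numpy as np
import pytest

from alvinest import cleaning, simulate


@pytest.fixture(scope="session")
def small_transcriptome():
    """A 30-gene transcriptome with uniform moderate expression."""
    return simulate.generate_transcriptome(30, seed=101, copy_numbers=[8] * 30)


@pytest.fixture(scope="session")
def noiseless_reads(small_transcriptome):
    params = simulate.ReadSimParams(
        seed=102, error_rate=0.0, vector_rate=0.0, polya_rate=0.0
    )
    return simulate.generate_reads(small_transcriptome, params)


def make_read(seq: str, qual=None, read_id: str = "r1") -> cleaning.QualityRead:
    if qual is None:
        qual = np.full(len(seq), 40)
    return cleaning.QualityRead(id=read_id, seq=seq, qual=np.asarray(qual))


@pytest.fixture
def read_factory():
    return make_read
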