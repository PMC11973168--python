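import numpy as np
import pytest

from skewdomain.model import GenomeSequence, GenomicInterval


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_genome():
    return GenomeSequence({"chr1": "ACGTACGTACGTACGTACGT"}, label="reference")


@pytest.fixture
def interval():
    return GenomicInterval("chr1", 100, 200)
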