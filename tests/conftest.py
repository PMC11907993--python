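import numpy as np
import pytest

from smadscan.grammar import CANONICAL_ELEMENTS


@pytest.fixture(scope="session")
def elements():
    return CANONICAL_ELEMENTS


@pytest.fixture()
def rng():
    return np.random.default_rng(20240313)


def random_dna(rng, length, gc=0.41):
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(rng.choice(list("ACGT"), size=length, p=p))
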