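import numpy as np
import pytest

from canerv.synthetic import make_ltr_consensus, make_proviral_consensus, random_dna


@pytest.fixture(scope="session")
def ltr():
    """A 457-bp LTR consensus shared by junction/dating fixtures."""
    return make_ltr_consensus(42)


@pytest.fixture(scope="session")
def consensus_model():
    """A full proviral consensus with clean gag/pol/env ORFs."""
    from canerv.provirus import ConsensusModel

    seq, genes, ltrs = make_proviral_consensus(7)
    return ConsensusModel(seq, genes, ltrs)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def genome40(rng):
    """40 kb of random genomic background for mapper/junction tests."""
    return random_dna(rng, 40_000)
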