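import numpy as np
import pytest

from famevol.synthetic import paper_fixture


@pytest.fixture(scope="session")
def tree6():
    """The calibrated 6-taxon great-ape Y tree (branch lengths in ky)."""
    return paper_fixture("tree6")


@pytest.fixture(scope="session")
def tree5():
    """The 5-taxon expression tree (Sumatran orangutan excluded)."""
    return paper_fixture("tree5")


@pytest.fixture()
def rng():
    return np.random.default_rng(20260925)
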