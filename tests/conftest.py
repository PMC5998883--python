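import logging

import numpy as np
import pytest

from kshrink import parse_newick
from kshrink.simulate import random_tree

TOY_NEWICK = "((A:1,B:1):1,(C:1,D:10):1);"


@pytest.fixture(autouse=True)
def _quiet_warnings_log(caplog):
    """Silence expected abstention/exemption warnings in bulk simulations."""
    logging.getLogger("kshrink").setLevel(logging.ERROR)
    yield
    logging.getLogger("kshrink").setLevel(logging.NOTSET)


@pytest.fixture
def toy_tree():
    """4-leaf tree with diameter pair (A, D) at distance 13."""
    return parse_newick(TOY_NEWICK)


@pytest.fixture
def rng():
    return np.random.default_rng(20240517)


@pytest.fixture
def make_random_tree(rng):
    """Factory for generic-branch-length random trees (singly paired a.s.)."""

    def make(n, mean=1.0):
        return random_tree([f"L{i:02d}" for i in range(n)], rng, mean)

    return make
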