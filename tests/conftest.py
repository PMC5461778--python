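import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # tests/oracles.py

from aptastack.folding import ReferenceBackend
from aptastack.selex_io import SequencePool
from aptastack.template import expected_insert


@pytest.fixture(scope="session")
def backend():
    """One shared reference backend so fold caches persist across tests."""
    return ReferenceBackend()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_insert(rng) -> str:
    var = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 30)])
    return expected_insert(var)


@pytest.fixture()
def small_pool(rng):
    """A pool of 50 random full-length inserts with mixed counts."""
    pool = SequencePool(round="11")
    for i in range(50):
        pool.add(random_insert(rng), count=int(rng.integers(1, 5)))
    return pool
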