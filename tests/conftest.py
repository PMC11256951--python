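import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from nmftrack.abundance_io import AbundanceTable
from nmftrack.simulate import synth_source_pool


@pytest.fixture
def rng():
    return np.random.default_rng(20240301)


@pytest.fixture
def tiny_sources():
    """Two orthogonal single-taxon sources over two taxa."""
    return AbundanceTable(("taxA", "taxB"), ("s1", "s2"), np.eye(2))


@pytest.fixture(scope="session")
def small_pool():
    """A compact sparse pool shared by the simulation unit tests."""
    return synth_source_pool(n_taxa=400, n_sources=60, sparsity=0.08, seed=11)
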