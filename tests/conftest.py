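import numpy as np
import pytest

from ampliclone.example import example_layout


@pytest.fixture(scope="session")
def layout():
    """The packaged synthetic 12x8 layout (200 bp amplicon, cut at 100)."""
    return example_layout()


@pytest.fixture(scope="session")
def small_layout():
    """A 3x2 partial plate for cheap combinatorial tests."""
    return example_layout(n_columns=3, n_rows=2)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
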