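import numpy as np
import pytest

from cnloh.genome import make_marker_map


@pytest.fixture(scope="session")
def dense_map():
    """250K-array-like marker density (~252k markers genome-wide)."""
    return make_marker_map(marker_spacing_bp=12_000)


@pytest.fixture(scope="session")
def sparse_map():
    """~20k markers genome-wide (50K-array-like)."""
    return make_marker_map(marker_spacing_bp=155_000)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
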