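import numpy as np
import pytest

from envi.data import SpatialDataset
from envi.synthetic import generate_tissue


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_tissue():
    """Small paired tissue shared by the cheap unit tests."""
    return generate_tissue(
        n_spatial=300, n_sc=300, g_panel=24, g_total=72, n_zones=3, seed=7
    )


@pytest.fixture()
def grid_dataset():
    """5x5 unit grid with two smooth genes, for niche/graph geometry tests."""
    xs, ys = np.meshgrid(np.arange(5.0), np.arange(5.0))
    coords = np.column_stack([xs.ravel(), ys.ravel()])
    counts = np.column_stack([coords[:, 0] + 1.0, 4.0 - coords[:, 1] + 1.0])
    return SpatialDataset(
        counts=counts, coords=coords, gene_names=np.array(["ga", "gb"], dtype=object)
    )
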