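import numpy as np
import pandas as pd
import pytest

from strokenet import ConnectivityMatrix, RegionAtlas


@pytest.fixture(scope="session")
def default_atlas():
    return RegionAtlas.default()


@pytest.fixture
def tiny_atlas_factory():
    """Build an n-region atlas with unit volumes for metric tests."""

    def make(n, volumes=None):
        return RegionAtlas(
            pd.DataFrame(
                {
                    "region_id": np.arange(1, n + 1),
                    "name": [f"region {i}" for i in range(n)],
                    "abbreviation": [f"r{i}" for i in range(n)],
                    "hemisphere": ["L"] * (n // 2) + ["R"] * (n - n // 2),
                    "volume_mm3": volumes if volumes is not None else [1.0] * n,
                }
            )
        )

    return make


@pytest.fixture
def matrix_factory(tiny_atlas_factory):
    """ConnectivityMatrix from an edge list or a dense array."""

    def from_edges(n, edges):
        w = np.zeros((n, n))
        for i, j, wt in edges:
            w[i, j] = w[j, i] = wt
        return ConnectivityMatrix(w, tiny_atlas_factory(n))

    return from_edges


@pytest.fixture
def random_matrix_factory(tiny_atlas_factory):
    """Random symmetric nonnegative weighted graph on n nodes."""

    def make(n, density=0.4, seed=0, unit_weights=False):
        rng = np.random.default_rng(seed)
        w = np.zeros((n, n))
        iu = np.triu_indices(n, k=1)
        present = rng.random(len(iu[0])) < density
        vals = np.ones(len(iu[0])) if unit_weights else rng.lognormal(0.0, 0.6, len(iu[0]))
        w[iu] = present * vals
        w = w + w.T
        return ConnectivityMatrix(w, tiny_atlas_factory(n))

    return make
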