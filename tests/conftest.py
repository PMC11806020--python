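import numpy as np
import pytest

from tauvuln import miss, synth


@pytest.fixture(scope="session")
def atlas60():
    """60 contiguous regions on a 12 x 12 x 10 grid (1440 voxels)."""
    return synth.generate_atlas(60, (12, 12, 10), rng_seed=7)


@pytest.fixture(scope="session")
def small_world():
    """A compact synthetic study reused by read-only tests."""
    return synth.generate_world(n_regions=60, grid_shape=(12, 12, 10),
                                n_genes=150, n_types=8, markers_per_type=8,
                                n_datasets=4, rng_seed=11)


@pytest.fixture(scope="session")
def small_world_densities(small_world):
    """MISS-inferred voxel and regional densities for the small world."""
    D_vox, D_reg, state = miss.run_miss(small_world.signatures,
                                        small_world.expression, n_genes=60)
    return D_vox, D_reg, state


@pytest.fixture
def rng():
    return np.random.default_rng(0)
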