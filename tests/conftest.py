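import numpy as np
import pytest

from foodspec import (
    BinnedSpectrum,
    FoodDB,
    SimConfig,
    Solvent,
    dataset_to_db,
    grid_for,
    make_dataset,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20160036)


@pytest.fixture(params=["D2O", "CDCl3"])
def grid(request):
    return grid_for(request.param)


@pytest.fixture
def d2o_grid():
    return grid_for(Solvent.D2O)


def random_spectrum(grid, rng, name="s", normalized=False):
    v = rng.gamma(0.3, 1.0, grid.n_bins)
    s = BinnedSpectrum(grid=grid, intensities=v, name=name)
    if normalized:
        from foodspec import preprocess

        return preprocess(s)
    return s


@pytest.fixture
def make_random_spectrum(rng):
    counter = [0]

    def factory(grid, normalized=False):
        counter[0] += 1
        return random_spectrum(grid, rng, name=f"rand_{counter[0]:03d}",
                               normalized=normalized)

    return factory


@pytest.fixture(scope="session")
def small_dataset():
    """Two-cluster synthetic dataset shared across read-only tests."""
    return make_dataset(SimConfig(seed=7, n_per_group=12))


@pytest.fixture(scope="session")
def small_db(small_dataset):
    db = dataset_to_db(small_dataset)
    yield db
    db.close()


@pytest.fixture
def empty_db():
    db = FoodDB()
    yield db
    db.close()
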