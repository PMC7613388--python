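import numpy as np
import pytest

import npvret as nv


def random_leaf(rng) -> nv.LeafParams:
    return nv.LeafParams(*(rng.uniform(lo, hi)
                           for lo, hi in nv.LeafParams.BOUNDS.values()))


def random_canopy(rng) -> nv.CanopyParams:
    return nv.CanopyParams(*(rng.uniform(lo, hi)
                             for lo, hi in nv.CanopyParams.BOUNDS.values()))


@pytest.fixture(scope="session")
def sensor():
    return nv.prisma_like_sensor()


@pytest.fixture(scope="session")
def small_db(sensor):
    """200 simulated samples on the sensor grid (shared, do not mutate)."""
    return nv.build_training_set(n=200, seed=11, sensor=sensor)


@pytest.fixture(scope="session")
def basis(small_db):
    return nv.fit_pca(small_db.wavelengths, small_db.spectra, n_components=20)


@pytest.fixture(scope="session")
def db_features(small_db, basis):
    return nv.features_from_full_grid(basis, small_db.wavelengths,
                                      small_db.spectra)


@pytest.fixture(scope="session")
def insitu_records():
    return nv.make_synthetic_insitu(n=14, seed=5)


@pytest.fixture(scope="session")
def small_scene():
    """30x30 patchwork scene with ground truth."""
    return nv.make_synthetic_scene(nv.default_scene_spec(rows=30, cols=30,
                                                         seed=3))
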