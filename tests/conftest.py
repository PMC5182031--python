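import numpy as np
import pytest

from fixel.core import FixelGrid
from fixel.fod import default_mesh
from fixel.phantom import PhantomSpec, make_phantom


@pytest.fixture(scope="session")
def mesh():
    return default_mesh()


@pytest.fixture(scope="session")
def spec():
    return PhantomSpec()


@pytest.fixture(scope="session")
def phantom_grid(spec):
    return make_phantom(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def small_grid():
    """3x2x1 grid with 0-2 fixels per voxel and an 'fd' value."""
    per_voxel = {
        (0, 0, 0): [(np.array([1.0, 0.0, 0.0]), {"fd": 0.5}),
                    (np.array([0.0, 1.0, 0.0]), {"fd": 0.3})],
        (1, 1, 0): [(np.array([0.0, 0.0, 1.0]), {"fd": 0.9})],
        (2, 0, 0): [(np.array([1.0, 1.0, 0.0]) / np.sqrt(2), {"fd": 0.7})],
    }
    return FixelGrid.from_voxel_lists((3, 2, 1), np.eye(4), per_voxel,
                                      values_names=["fd"])


def random_fixel_grid(rng, shape=(3, 3, 1), max_fixels=3, values=("fd",)):
    """Random valid fixel grid for property tests."""
    per_voxel = {}
    for vox in np.ndindex(shape):
        n = int(rng.integers(0, max_fixels + 1))
        fx = []
        for _ in range(n):
            d = rng.normal(size=3)
            d /= np.linalg.norm(d)
            fx.append((d, {v: float(rng.uniform(0.1, 1.0)) for v in values}))
        if fx:
            per_voxel[vox] = fx
    return FixelGrid.from_voxel_lists(shape, np.eye(4), per_voxel,
                                      values_names=list(values))
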