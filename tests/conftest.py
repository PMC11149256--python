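import numpy as np
import pytest

from tau3d import BinaryVolume, make_cube, make_sphere


@pytest.fixture
def rng():
    return np.random.default_rng(20240604)


@pytest.fixture(scope="session")
def cube41():
    return make_cube(41)


@pytest.fixture(scope="session")
def sphere12():
    return make_sphere(12)


@pytest.fixture
def single_voxel():
    grid = np.zeros((5, 5, 5), dtype=bool)
    grid[2, 2, 2] = True
    return BinaryVolume(grid)


def random_mask(rng, max_side=12):
    """Random small binary mask, occasionally sparse, occasionally dense."""
    h = int(rng.integers(1, max_side + 1))
    w = int(rng.integers(1, max_side + 1))
    density = rng.uniform(0.2, 0.8)
    return rng.random((h, w)) < density


def random_convex_polygon(rng, n_max=12):
    """Random convex polygon: points on an ellipse at sorted random angles."""
    n = int(rng.integers(3, n_max + 1))
    angles = np.sort(rng.uniform(0, 2 * np.pi, size=n))
    # reject near-duplicate angles that would create degenerate edges
    while np.min(np.diff(np.concatenate([angles, [angles[0] + 2 * np.pi]]))) < 1e-3:
        angles = np.sort(rng.uniform(0, 2 * np.pi, size=n))
    a, b = rng.uniform(1, 10, size=2)
    return np.column_stack([a * np.cos(angles), b * np.sin(angles)])
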