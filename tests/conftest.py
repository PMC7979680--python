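import numpy as np
import pytest

from morphhead import ImageVolume, VectorField
from morphhead.synthetic import PhantomSpec, make_head_phantom, make_hex_lattice

UNIT_CUBE = np.array(
    [
        [0, 0, 0],
        [1, 0, 0],
        [1, 1, 0],
        [0, 1, 0],
        [0, 0, 1],
        [1, 0, 1],
        [1, 1, 1],
        [0, 1, 1],
    ],
    dtype=float,
)


@pytest.fixture(scope="session")
def unit_cube():
    return UNIT_CUBE.copy()


@pytest.fixture(scope="session")
def lattice10():
    """10³ unit-cube lattice."""
    return make_hex_lattice(10, 10, 10, spacing=1.0)


@pytest.fixture(scope="session")
def phantom():
    """Default 64³ head phantom (seeded noise)."""
    return make_head_phantom(PhantomSpec(seed=7))


@pytest.fixture(scope="session")
def small_phantom():
    """Smaller 48³ phantom for registration unit tests."""
    spec = PhantomSpec(shape=(48, 48, 48), spacing=4.0, seed=3)
    return make_head_phantom(spec)


def constant_field(shape, spacing, vec, convention="resampling"):
    affine = np.diag([spacing, spacing, spacing, 1.0])
    data = np.tile(np.asarray(vec, dtype=float), (*shape, 1))
    return VectorField(data, affine, convention)


def affine_field(shape, spacing, A, b, convention="resampling"):
    """u(x) = A x + b sampled on the grid."""
    affine = np.diag([spacing, spacing, spacing, 1.0])
    idx = np.indices(shape, dtype=float)
    pts = np.stack([c.ravel() for c in idx], axis=1) * spacing
    u = pts @ np.asarray(A, float).T + np.asarray(b, float)
    return VectorField(u.reshape(*shape, 3), affine, convention)


def ball_mask(shape, spacing, center, radius):
    affine = np.diag([spacing, spacing, spacing, 1.0])
    idx = np.indices(shape, dtype=float)
    pts = np.stack(idx, axis=-1) * spacing
    m = ((pts - np.asarray(center)) ** 2).sum(axis=-1) <= radius ** 2
    return ImageVolume(m.astype(np.uint8), affine, is_mask=True)
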