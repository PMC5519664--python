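import numpy as np
import pytest

from flowpost.io_grids.types import BinaryMask, GridGeometry, VelocityField
from flowpost.synthetic import PhantomSpec, gen_phantom


@pytest.fixture
def unit_grid():
    """Small isotropic grid, 1 mm spacing, origin at zero."""
    return GridGeometry(shape=(8, 8, 8), spacing=(1.0, 1.0, 1.0))


@pytest.fixture
def ball_mask():
    """Voxelized ball of radius 10 mm at 1 mm spacing, centered."""
    geometry = GridGeometry(shape=(25, 25, 25), spacing=(1.0, 1.0, 1.0),
                            origin=(-12.0, -12.0, -12.0))
    r = np.linalg.norm(geometry.voxel_centers(), axis=-1)
    return BinaryMask(geometry, r <= 10.0)


@pytest.fixture(scope="session")
def poiseuille_1mm():
    """Poiseuille pipe R=10 mm, L=100 mm, Q=5 L/min at 1 mm spacing."""
    spec = PhantomSpec(kind="poiseuille", radius=10.0, length=100.0,
                       flow_rate_lpm=5.0, spacing=(1.0, 1.0, 1.0))
    return gen_phantom(spec)


def uniform_field(geometry, velocity):
    values = np.zeros((*geometry.shape, 3))
    values[:] = np.asarray(velocity, dtype=float)
    return VelocityField(geometry=geometry, values=values[None])


def linear_field(geometry, matrix, offset=(0.0, 0.0, 0.0)):
    """v(x) = matrix @ x + offset with x in metres."""
    centers_m = geometry.voxel_centers() * 1e-3
    values = centers_m @ np.asarray(matrix, dtype=float).T + np.asarray(offset)
    return VelocityField(geometry=geometry, values=values[None])
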