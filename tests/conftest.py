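import numpy as np
import pytest

from fetrelapse import PhantomConfig, generate_case, generate_cohort
from fetrelapse.grid import BinaryMask, GridSpec, ScalarVolume


@pytest.fixture(scope="session")
def phantom_case():
    """One noise-free default phantom with its ground truth."""
    return generate_case(PhantomConfig())


@pytest.fixture(scope="session")
def phantom_cohort():
    """A 13-case noise-free phantom cohort (2 mm grid), jittered around defaults."""
    return generate_cohort(PhantomConfig(), 13, seed=11)


@pytest.fixture()
def unit_grid():
    """1 mm isotropic 32^3 grid for analytic desk checks."""
    return GridSpec(shape=(32, 32, 32), spacing=(1.0, 1.0, 1.0))


def make_sphere_mask(grid: GridSpec, center_mm, radius_mm) -> BinaryMask:
    coords = [
        np.arange(n) * s + o
        for n, s, o in zip(grid.shape, grid.spacing, grid.origin)
    ]
    xx, yy, zz = np.meshgrid(*coords, indexing="ij")
    c = np.asarray(center_mm, dtype=float)
    d2 = (xx - c[0]) ** 2 + (yy - c[1]) ** 2 + (zz - c[2]) ** 2
    return BinaryMask(grid, d2 <= radius_mm**2)


def make_uniform_volume(grid: GridSpec, value: float) -> ScalarVolume:
    return ScalarVolume(grid, np.full(grid.shape, value, dtype=float))
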