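import numpy as np
import pytest

from ringdose.grid import StructureSet, VoxelGrid
from ringdose.phantom import PhantomParams


def sphere_mask(grid: VoxelGrid, center_mm, radius_mm) -> np.ndarray:
    xs, ys, zs = grid.voxel_centers_mm()
    r2 = ((xs - center_mm[0])[:, None, None] ** 2
          + (ys - center_mm[1])[None, :, None] ** 2
          + (zs - center_mm[2])[None, None, :] ** 2)
    return r2 <= radius_mm**2


@pytest.fixture
def unit_grid():
    """1 mm isotropic 64^3 lattice."""
    return VoxelGrid(shape=(64, 64, 64), spacing_mm=(1.0, 1.0, 1.0))


@pytest.fixture
def sphere_structures(unit_grid):
    """HR-CTV sphere r=12 mm with a 16-22 mm shell OAR around it."""
    c = (32.0, 32.0, 32.0)
    hrctv = sphere_mask(unit_grid, c, 12.0)
    oar = sphere_mask(unit_grid, c, 22.0) & ~sphere_mask(unit_grid, c, 16.0)
    return StructureSet(grid=unit_grid, masks={"hrctv": hrctv, "rectum": oar})


@pytest.fixture(scope="session")
def fast_params():
    """Coarse (3 mm) phantom lattice: same 192 mm extent, 27x fewer voxels."""
    return PhantomParams(shape=(64, 64, 64), spacing_mm=(3.0, 3.0, 3.0), seed=11)
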