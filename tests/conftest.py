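import numpy as np
import pytest
from hypothesis import settings

from invpetdose import phantom, projection, study

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def disc_setup():
    """Uniform 20 mm radius disc at concentration 5 on a 64x64 1 mm grid."""
    grid = phantom.GridSpec(nx=64, ny=64, nz=1, dx=1.0, dy=1.0, dz=1.0)
    x = grid.axis_coords("x")[:, None]
    y = grid.axis_coords("y")[None, :]
    disc = ((x**2 + y**2) <= 20.0**2).astype(float) * 5.0
    amap = phantom.ActivityMap(disc[:, :, None], grid)
    geom = projection.ScanGeometry.for_grid(grid, n_angles=96)
    sino = projection.forward_project(amap, geom)
    return grid, amap, geom, sino


@pytest.fixture(scope="session")
def small_phantom():
    """Full NU4 phantom voxelized on the compact study grid."""
    grid = study.default_study_grid()
    amap, mumap, labels, geometry = phantom.build_nu4_phantom(grid=grid)
    return grid, amap, mumap, labels, geometry


@pytest.fixture(scope="session")
def phantom_study_seed42():
    """One noisy acquisition (5e6 counts, seed 42) scored for the
    whole reconstruction family at both correction levels."""
    return study.run_phantom_study(seed=42, total_counts=5e6)
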