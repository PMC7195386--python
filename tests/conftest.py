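import numpy as np
import pytest

from emish3d import PhantomSpec, generate_phantom
from emish3d.imagestack import VoxelGrid


@pytest.fixture(scope="session")
def small_phantom():
    """A compact 3-lobe phantom with specks (fast to generate, reused widely)."""
    return generate_phantom(PhantomSpec(n_domains=3, seed=11))


@pytest.fixture(scope="session")
def single_lobe_phantom():
    """One clean lobe, no specks, no detector noise."""
    return generate_phantom(PhantomSpec(
        shape=(16, 120, 120), n_domains=1, speckle_count=0, noise_sd=0.0, seed=5))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def digitized_ball(radius_vox: int, voxel_nm: float = 5.0) -> VoxelGrid:
    """Binary ball of given voxel radius on an isotropic grid (as intensities)."""
    n = 2 * radius_vox + 5
    c = (n - 1) / 2
    z, y, x = np.indices((n, n, n))
    ball = ((z - c) ** 2 + (y - c) ** 2 + (x - c) ** 2) <= radius_vox ** 2
    return VoxelGrid(ball.astype(np.uint8) * 200, (voxel_nm,) * 3)
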