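import sys
from pathlib import Path

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from fuzzyroi import ImageVolume, PhantomSpec, generate_phantom


@pytest.fixture(scope="session")
def standard_phantom():
    """The default 3x64x64 phantom: volume (lung mask attached), truth, lung."""
    return generate_phantom(PhantomSpec())


@pytest.fixture()
def rng():
    return np.random.default_rng(20160718)


@pytest.fixture()
def small_volume(rng):
    """A 1x6x6 HU-range random slice, no lung mask."""
    vox = rng.uniform(-1000, 100, size=(1, 6, 6))
    return ImageVolume(voxels=vox)


@pytest.fixture()
def small_volume_3d(rng):
    """A 3x5x5 HU-range random volume."""
    vox = rng.uniform(-1000, 100, size=(3, 5, 5))
    return ImageVolume(voxels=vox)


@pytest.fixture()
def masked_volume(rng):
    """A 2x6x6 volume with an irregular lung mask."""
    vox = rng.uniform(-1000, 100, size=(2, 6, 6))
    mask = rng.random((2, 6, 6)) > 0.3
    mask[0, 0, 0] = True  # keep at least one voxel per slice deterministic
    mask[1, 0, 0] = True
    return ImageVolume(voxels=vox, lung_mask=mask)


def random_memberships(rng, c, n):
    """Valid random membership matrix: columns in the simplex."""
    u = rng.random((c, n)) + 1e-6
    return u / u.sum(axis=0)
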