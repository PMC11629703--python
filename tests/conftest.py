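import numpy as np
import pytest

import wmhlnm as w
from wmhlnm.lnm import functional_seed_maps, structural_seed_maps


@pytest.fixture(scope="session")
def toy_parc():
    return w.make_toy_brain(w.ToyBrainConfig(), seed=11)


@pytest.fixture(scope="session")
def small_connectome(toy_parc):
    return w.simulate_functional_connectome(toy_parc, S=6, T=60, seed=12)


@pytest.fixture(scope="session")
def seed_maps(toy_parc, small_connectome):
    return functional_seed_maps(toy_parc, small_connectome)


@pytest.fixture(scope="session")
def structural_maps(toy_parc):
    vols = w.simulate_structural_streamline_map(toy_parc, seed=13)
    return structural_seed_maps(toy_parc, vols)


@pytest.fixture(scope="session")
def small_cohort():
    """Desk-scale cohort reused across modules (n kept small for speed)."""
    return w.simulate_cohort(n_patients=60, seed=21)


def make_volume(data, voxel_size=1.0, origin=None):
    data = np.asarray(data)
    if origin is None:
        vs = np.broadcast_to(np.asarray(voxel_size, float), (3,))
        origin = tuple(-(d - 1) / 2 * v for d, v in zip(data.shape, vs))
    return w.Volume3D(data, voxel_size, origin)


def make_mask(data, voxel_size=1.0, origin=None):
    vol = make_volume(data, voxel_size, origin)
    return w.BinaryMask(vol.data, vol.voxel_size, vol.origin)
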