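import numpy as np
import pytest

from connmap.sim import NetworkSpec, SimConfig, _box, generate_study
from connmap.volumes import BoldRun, NetworkMask, VolumeGeometry


@pytest.fixture(scope="session")
def geom_small():
    return VolumeGeometry.isotropic((10, 10, 6), voxel_mm=2.0, world_convention="right_positive_x")


@pytest.fixture(scope="session")
def tiny_config():
    """One 100-voxel network on a 10x10x6 grid; 4 subjects, 80 frames."""
    return SimConfig(
        n_subjects=4,
        n_frames=80,
        grid_shape=(10, 10, 6),
        conditions=("sham", "cTBS"),
        network_specs=[NetworkSpec("net", _box(2, 7, 2, 7, 1, 5), 0.4)],
        seed=42,
    )


@pytest.fixture(scope="session")
def tiny_study(tiny_config):
    return generate_study(tiny_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def make_run(data, voxel_mm=2.0, tr_s=0.5, censored=(), subject="s0", condition="c"):
    data = np.asarray(data, dtype=float)
    geom = VolumeGeometry.isotropic(data.shape[:3], voxel_mm)
    return BoldRun(
        geometry=geom,
        data=data,
        tr_s=tr_s,
        censored_frames=frozenset(censored),
        subject_id=subject,
        condition=condition,
    )


def box_mask(geom, i0, i1, j0, j1, k0, k1, name="m"):
    ind = np.zeros(geom.shape, dtype=bool)
    ind[i0:i1, j0:j1, k0:k1] = True
    return NetworkMask(geom, ind, name=name)
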