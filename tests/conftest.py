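import numpy as np
import pytest

import chiroscat as cs


@pytest.fixture(scope="session")
def default_spec():
    """Standard one-turn solenoid: R=10 nm, P=11 nm, 6 cylinders per turn."""
    return cs.SolenoidSpec()


@pytest.fixture(scope="session")
def mini_helix_model(default_spec):
    """Coarse (10 dipoles/longest) voxelization of the standard solenoid."""
    poses = cs.nucleosome_poses(default_spec)
    return cs.voxelize(poses, default_spec.shape, 10)


@pytest.fixture(scope="session")
def random_lattice_model():
    """50 random occupied sites on a 10^3 lattice (seeded)."""
    rng = np.random.default_rng(1234)
    flat = rng.choice(1000, size=50, replace=False)
    sites = np.stack(np.unravel_index(flat, (10, 10, 10)), axis=1)
    return cs.DipoleModel(spacing=1.5, origin=np.zeros(3), sites=sites, rel_index=1.68 / 1.33)


@pytest.fixture(scope="session")
def default_wave():
    return cs.PlaneWave()
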