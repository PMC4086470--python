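import numpy as np
import pytest

from ossidrive import fem, materials
from ossidrive.middle_ear import build_default_network


@pytest.fixture(scope="session")
def pzt4_mat():
    return materials.pzt4()


@pytest.fixture(scope="session")
def d_matrix(pzt4_mat):
    """Strain constants from direct inversion of the stiffness table."""
    return materials.derive_strain_constants(pzt4_mat)


@pytest.fixture(scope="session")
def default_network():
    return build_default_network()


@pytest.fixture
def small_stack(pzt4_mat):
    """Coarse 4-layer stack system with electrodes at 1 V (fast)."""
    spec = fem.StackSpec(n_layers=4, layer_thickness=0.5e-3,
                         width=2e-3, depth=2e-3, nx=2, ny=2, nz_per_layer=1)
    system = fem.assemble(fem.mesh_stack(spec), pzt4_mat, beta=1e-4)
    fem.apply_electrodes(system, 1.0)
    return system


def make_stack_system(mat, v_rms=1.0, **spec_kwargs):
    spec = fem.StackSpec(**spec_kwargs)
    system = fem.assemble(fem.mesh_stack(spec), mat, beta=1e-4)
    fem.apply_electrodes(system, v_rms)
    return system


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20140618)
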