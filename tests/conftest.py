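import numpy as np
import pytest

from gpcrdimer.model_io import Structure
from gpcrdimer.synthetic import (clozapine_like_monomer_spec,
                                 dimer_interface_spec,
                                 generate_dimer_trajectory,
                                 generate_monomer_trajectory)


@pytest.fixture
def rng():
    return np.random.default_rng(20260924)


def make_structure(atoms):
    """Build a Structure from (name, element, res_name, res_seq, chain, xyz,
    hetero) tuples, assigning serials in order."""
    n = len(atoms)
    return Structure(
        serial=np.arange(1, n + 1),
        name=np.array([a[0] for a in atoms], dtype=object),
        element=np.array([a[1] for a in atoms], dtype=object),
        res_name=np.array([a[2] for a in atoms], dtype=object),
        res_seq=np.array([a[3] for a in atoms]),
        chain_id=np.array([a[4] for a in atoms], dtype=object),
        xyz=np.array([a[5] for a in atoms], dtype=float),
        hetero=np.array([a[6] if len(a) > 6 else False for a in atoms]),
    )


@pytest.fixture(scope="session")
def monomer_run():
    """One moderately sized ligand-bound monomer with ground truth."""
    spec = clozapine_like_monomer_spec(seed=11, n_frames=300)
    traj, bw_map, truth = generate_monomer_trajectory(spec)
    return spec, traj, bw_map, truth


@pytest.fixture(scope="session")
def dimer_run():
    """One moderately sized homodimer trajectory with ground truth."""
    spec = dimer_interface_spec(seed=13, n_frames=250)
    traj, bw_map, truth = generate_dimer_trajectory(spec)
    return spec, traj, bw_map, truth
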