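import numpy as np
import pytest

from qensmd import (
    AtomRecord,
    SimulationCell,
    Trajectory,
    generate_brownian_trajectory,
    p_cresol_template,
)


def make_trajectory(positions, frame_interval=1.0, edge=40.0, b_inc=None, molecule_ids=None):
    """Small helper: trajectory from a raw position array with H-like atoms."""
    positions = np.asarray(positions, dtype=float)
    n_atoms = positions.shape[1]
    atoms = tuple(
        AtomRecord(
            atom_id=i,
            element="H",
            site_label="tracer",
            mass=1.008,
            b_inc=25.274 if b_inc is None else b_inc[i],
            molecule_id=i if molecule_ids is None else molecule_ids[i],
        )
        for i in range(n_atoms)
    )
    return Trajectory(
        positions=positions,
        frame_interval=frame_interval,
        cell=SimulationCell((edge, edge, edge)),
        atoms=atoms,
    )


@pytest.fixture(scope="session")
def template():
    return p_cresol_template()


@pytest.fixture(scope="session")
def brownian_traj():
    """1000 Brownian tracers at D = 5e-10 m²/s, 2000 frames at 1 ps."""
    return generate_brownian_trajectory(
        n_particles=1000, D_target=5e-10, n_frames=2000, seed=42
    )
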