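"""RDF normalization, coordination numbers, geometric hydrogen bonds."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from qensmd import (
    HBondCriteria,
    SimulationCell,
    compute_rdf,
    count_hbonds,
    hbond_angle_sweep,
    plant_hbond_configuration,
    rdf_first_minimum,
)
from qensmd.hbond import RDFResult, _min_image

from conftest import make_trajectory


def _ideal_gas_traj(n=800, edge=30.0, frames=10, seed=5):
    rng = np.random.default_rng(seed)
    pos = rng.uniform(0, edge, size=(frames, n, 3))
    return make_trajectory(pos, edge=edge)


def test_ideal_gas_rdf_is_unity():
    traj = _ideal_gas_traj()
    rdf = compute_rdf(traj, "H", "H", r_max=12.0, bin_width=0.25)
    far = rdf.r > 2.0
    np.testing.assert_allclose(rdf.g[far], 1.0, atol=0.05)
    assert np.all(np.diff(rdf.n) >= 0)


def test_two_fixed_atoms_give_single_bin_peak():
    pos = np.zeros((2, 2, 3))
    pos[:, 1, 0] = 3.0
    traj = make_trajectory(pos, edge=40.0)
    rdf = compute_rdf(traj, "H", "H", r_max=10.0, bin_width=0.1)
    peak_bin = np.argmax(rdf.g)
    assert rdf.r[peak_bin] == pytest.approx(3.05, abs=0.051)
    assert np.count_nonzero(rdf.g) == 1


def test_coordination_number_matches_brute_force():
    """n(r) at the cutoff equals a direct neighbor count / N_A."""
    traj = _ideal_gas_traj(n=300, frames=2, seed=9)
    r_cut = 3.5
    rdf = compute_rdf(traj, "H", "H", r_max=10.0, bin_width=0.05)
    idx = int(r_cut / 0.05)
    # brute force: average neighbors within all complete bins below r_cut
    total = 0
    for f in range(traj.n_frames):
        p = traj.positions[f]
        d = _min_image(p[:, None, :] - p[None, :, :], traj.cell)
        dist = np.linalg.norm(d, axis=2)
        np.fill_diagonal(dist, np.inf)
        total += np.count_nonzero(dist < idx * 0.05) / p.shape[0]
    assert rdf.n[idx - 1] == pytest.approx(total / traj.n_frames, abs=1e-9)


def test_rdf_rejects_oversized_rmax_and_empty_selection():
    traj = _ideal_gas_traj(n=10, frames=1)
    with pytest.raises(ValueError, match="half the smallest"):
        compute_rdf(traj, "H", "H", r_max=20.0)
    with pytest.raises(ValueError, match="matches no atoms"):
        compute_rdf(traj, "O", "H", r_max=10.0)


def test_rdf_translation_invariance():
    traj = _ideal_gas_traj(n=150, frames=1, seed=2)
    shifted = make_trajectory(np.mod(traj.positions + 17.3, 30.0), edge=30.0)
    a = compute_rdf(traj, "H", "H", r_max=10.0, bin_width=0.2)
    b = compute_rdf(shifted, "H", "H", r_max=10.0, bin_width=0.2)
    np.testing.assert_allclose(a.g, b.g, atol=1e-12)


def _dimer_fixture(angle_deg, d_oo=2.8):
    """Two minimal hydroxyl-bearing molecules with a controlled O-H-O angle."""
    from qensmd.synthetic import _donor_h_direction
    from qensmd.core import AtomRecord, Trajectory

    o1 = np.array([10.0, 10.0, 10.0])
    o2 = o1 + [d_oo, 0.0, 0.0]
    h1 = o1 + 0.96 * _donor_h_direction(d_oo, angle_deg)
    h2 = o2 + [0.96, 0.0, 0.0]  # acceptor H points away
    pos = np.stack([o1, h1, o2, h2])[None, :, :].repeat(2, axis=0)
    atoms = []
    for i, (el, lab, mol) in enumerate(
        [("O", "hydroxyl-O", 0), ("H", "hydroxyl-H", 0),
         ("O", "hydroxyl-O", 1), ("H", "hydroxyl-H", 1)]
    ):
        atoms.append(AtomRecord(i, el, lab, 15.999 if el == "O" else 1.008,
                                0.0 if el == "O" else 25.274, mol))
    return Trajectory(pos, 1.0, SimulationCell((40.0, 40.0, 40.0)), tuple(atoms))


def test_dimer_within_criteria_is_bonded():
    counts = count_hbonds(_dimer_fixture(175.0), HBondCriteria())
    assert counts.per_frame[0] == 1
    assert counts.bonds_per_molecule == pytest.approx(1.0)


def test_dimer_outside_angle_window_is_not_bonded():
    counts = count_hbonds(_dimer_fixture(150.0), HBondCriteria())
    assert counts.per_frame[0] == 0


def test_planted_configuration_counted_exactly():
    fixture = plant_hbond_configuration(40, 13, seed=21)
    counts = count_hbonds(fixture.trajectory)
    assert counts.per_frame[0] == 13
    assert counts.bonds_per_molecule == pytest.approx(13 / 20)


@settings(max_examples=10, deadline=None, derandomize=True)
@given(seed=st.integers(0, 1000))
def test_angle_sweep_non_decreasing(seed):
    n_bonds = seed % 8
    fixture = plant_hbond_configuration(20, n_bonds, seed=seed)
    sweep = hbond_angle_sweep(fixture.trajectory, cutoffs=(10, 20, 30, 40, 50, 60))
    assert np.all(np.diff(sweep) >= 0)
    # planted bonds sit at 175°, so every half-width >= 5° sees them all
    np.testing.assert_allclose(sweep, n_bonds / 10.0)


def test_angle_sweep_matches_brute_force_recount():
    fixture = plant_hbond_configuration(30, 9, seed=8)
    cutoffs = (10, 25, 40, 60)
    sweep = hbond_angle_sweep(fixture.trajectory, cutoffs=cutoffs)
    for k, c in enumerate(cutoffs):
        counts = count_hbonds(
            fixture.trajectory, HBondCriteria(oo_cutoff=3.5, angle_halfwidth=c)
        )
        assert sweep[k] == pytest.approx(counts.bonds_per_molecule)


def test_bonds_never_exceed_oo_coordination():
    """Per-molecule bonds are bounded by the O-O coordination number at the
    same cutoff: the angular criterion only removes pairs."""
    fixture = plant_hbond_configuration(24, 7, seed=6)
    counts = count_hbonds(fixture.trajectory, HBondCriteria())
    rdf = compute_rdf(
        fixture.trajectory, "hydroxyl-O", "hydroxyl-O", r_max=10.0, bin_width=0.05
    )
    n_at_cutoff = rdf.n[np.searchsorted(rdf.r, 3.5)]
    assert counts.bonds_per_molecule <= n_at_cutoff + 1e-9


def test_first_minimum_locator():
    r = np.arange(0.05, 8.0, 0.1)
    g = 1.0 + 2.0 * np.exp(-((r - 2.8) ** 2) / 0.08) - 0.6 * np.exp(-((r - 3.6) ** 2) / 0.08)
    rdf = RDFResult(r=r, g=g, n=np.cumsum(g))
    # analytic minimum of the two-Gaussian profile sits just past 3.6 Å
    assert rdf_first_minimum(rdf) == pytest.approx(3.62, abs=0.15)


def test_hbond_requires_hydroxyl_sites():
    traj = _ideal_gas_traj(n=4, frames=1)
    with pytest.raises(ValueError, match="hydroxyl"):
        count_hbonds(traj)
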