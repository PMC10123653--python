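"""Liquid-structure statistics: RDFs, coordination numbers, hydrogen bonds.

The radial distribution function is computed between two atom selections on
different molecules only, under the minimum-image convention, normalized by
the ideal-gas pair density; the running coordination number n(r) is its
cumulative integral (the mean number of B neighbours of an A atom within r).

A hydrogen bond is geometric: two hydroxyl oxygens on different molecules
closer than the O–O cutoff (default 3.5 Å, the first-minimum position of
the O–O RDF) with at least one of the two O–H···O angles — measured at the
hydrogen, as deviation from linearity — inside 180° ± the angular half-width
(default 20°).  Each O–O pair contributes at most one bond (the undirected
convention implied by normalizing per-molecule counts by N/2: two molecules
share one bond); the directed donor→acceptor count is also reported.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

from .core import SimulationCell, Trajectory

__all__ = [
    "HBondCriteria",
    "RDFResult",
    "HBondCounts",
    "compute_rdf",
    "count_hbonds",
    "hbond_angle_sweep",
    "rdf_first_minimum",
]


@dataclass(frozen=True)
class HBondCriteria:
    """Geometric hydrogen-bond definition."""

    oo_cutoff: float = 3.5          # Å
    angle_halfwidth: float = 20.0   # degrees about linear (180°)

    def __post_init__(self) -> None:
        if self.oo_cutoff <= 0:
            raise ValueError("oo_cutoff must be > 0")
        if not 0 < self.angle_halfwidth <= 90:
            raise ValueError("angle_halfwidth must be in (0, 90] degrees")


@dataclass
class RDFResult:
    r: np.ndarray   # bin centers, Å
    g: np.ndarray   # dimensionless
    n: np.ndarray   # running coordination number


@dataclass
class HBondCounts:
    per_frame: np.ndarray           # undirected bonds per frame
    bonds_per_molecule: float       # mean per frame / (N_molecules / 2)
    directed_per_frame: np.ndarray  # qualifying donor geometries per frame
    directed_per_molecule: float


def _selection_mask(traj: Trajectory, selection) -> np.ndarray:
    if isinstance(selection, str):
        mask = np.array(
            [a.site_label == selection or a.element == selection for a in traj.atoms]
        )
    else:
        mask = np.asarray(selection, dtype=bool)
    if not mask.any():
        raise ValueError(f"selection {selection!r} matches no atoms")
    return mask


def _min_image(delta: np.ndarray, cell: SimulationCell) -> np.ndarray:
    if not cell.periodic:
        return delta
    edges = cell.edges
    return delta - edges * np.round(delta / edges)


def compute_rdf(
    traj: Trajectory,
    selection_A,
    selection_B,
    r_max: float = 10.0,
    bin_width: float = 0.05,
) -> RDFResult:
    """Intermolecular radial distribution function g(r) and its running
    coordination number n(r) between two selections.

    Selections are site labels, element symbols, or boolean masks.  Pairs on
    the same molecule are excluded; distances use the minimum-image
    convention, so ``r_max`` must not exceed half the smallest cell edge.
    """
    if traj.cell.periodic and r_max > min(traj.cell.edge_lengths) / 2.0:
        raise ValueError(
            f"r_max {r_max} Å exceeds half the smallest cell edge "
            f"{min(traj.cell.edge_lengths) / 2.0} Å"
        )
    mask_a = _selection_mask(traj, selection_A)
    mask_b = _selection_mask(traj, selection_B)
    mol = traj.molecule_ids()
    mol_a, mol_b = mol[mask_a], mol[mask_b]
    diff_mol = mol_a[:, None] != mol_b[None, :]

    edges_grid = np.arange(0.0, r_max + bin_width, bin_width)
    hist = np.zeros(edges_grid.size - 1)
    for f in range(traj.n_frames):
        pa = traj.positions[f, mask_a]
        pb = traj.positions[f, mask_b]
        delta = _min_image(pa[:, None, :] - pb[None, :, :], traj.cell)
        dist = np.linalg.norm(delta, axis=2)[diff_mol]
        hist += np.histogram(dist, bins=edges_grid)[0]

    n_a, n_b = int(mask_a.sum()), int(mask_b.sum())
    rho_b = n_b / traj.cell.volume
    shell_vol = 4.0 / 3.0 * np.pi * (edges_grid[1:] ** 3 - edges_grid[:-1] ** 3)
    norm = traj.n_frames * n_a * rho_b * shell_vol
    g = hist / norm
    n_running = np.cumsum(hist) / (traj.n_frames * n_a)
    centers = 0.5 * (edges_grid[1:] + edges_grid[:-1])
    return RDFResult(r=centers, g=g, n=n_running)


def _hydroxyl_sites(traj: Trajectory) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-molecule indices of the hydroxyl O and its bonded H."""
    mol = traj.molecule_ids()
    unique = np.unique(mol)
    o_idx = np.full(unique.size, -1)
    h_idx = np.full(unique.size, -1)
    pos = {m: i for i, m in enumerate(unique)}
    for i, a in enumerate(traj.atoms):
        if a.site_label == "hydroxyl-O":
            o_idx[pos[a.molecule_id]] = i
        elif a.site_label == "hydroxyl-H":
            h_idx[pos[a.molecule_id]] = i
    missing = unique[(o_idx < 0) | (h_idx < 0)]
    if missing.size:
        raise ValueError(
            f"molecules {missing.tolist()} lack a hydroxyl-O/hydroxyl-H site pair"
        )
    return unique, o_idx, h_idx


def _pair_geometry(traj: Trajectory, frame: int):
    """All intermolecular O–O distances and the two O–H···O deviations from
    linearity (degrees) for each oxygen pair, minimum-image consistent."""
    _, o_idx, h_idx = _hydroxyl_sites(traj)
    cell = traj.cell
    o = traj.positions[frame, o_idx]
    h = traj.positions[frame, h_idx]
    n = o.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    d_oo_vec = _min_image(o[ju] - o[iu], cell)          # O_i -> O_j image
    dist = np.linalg.norm(d_oo_vec, axis=1)

    def deviation(o_own, h_own, o_other_vec):
        # angle at H between (O_own - H) and (O_other - H); 0° deviation = linear
        oh = _min_image(h_own - o_own, cell)            # O -> H
        v1 = -oh                                        # H -> O_own
        v2 = o_other_vec - oh                           # H -> O_other (same image frame)
        cosang = np.einsum("ij,ij->i", v1, v2) / (
            np.linalg.norm(v1, axis=1) * np.linalg.norm(v2, axis=1)
        )
        ang = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
        return np.abs(180.0 - ang)

    dev_i = deviation(o[iu], h[iu], d_oo_vec)           # donor = molecule i
    dev_j = deviation(o[ju], h[ju], -d_oo_vec)          # donor = molecule j
    return dist, dev_i, dev_j, n


def count_hbonds(traj: Trajectory, criteria: HBondCriteria | None = None) -> HBondCounts:
    """Count geometric hydrogen bonds per frame and per molecule.

    Per-molecule mean = (mean undirected bonds per frame) / (N/2): two
    molecules share each bond, so N/2 bonds saturate at one per molecule.
    """
    if criteria is None:
        criteria = HBondCriteria()
    per_frame = np.zeros(traj.n_frames)
    directed = np.zeros(traj.n_frames)
    n_mol = 0
    for f in range(traj.n_frames):
        dist, dev_i, dev_j, n_mol = _pair_geometry(traj, f)
        close = dist < criteria.oo_cutoff
        ok_i = close & (dev_i <= criteria.angle_halfwidth)
        ok_j = close & (dev_j <= criteria.angle_halfwidth)
        per_frame[f] = np.count_nonzero(ok_i | ok_j)
        directed[f] = np.count_nonzero(ok_i) + np.count_nonzero(ok_j)
    half_n = n_mol / 2.0
    return HBondCounts(
        per_frame=per_frame,
        bonds_per_molecule=float(per_frame.mean() / half_n),
        directed_per_frame=directed,
        directed_per_molecule=float(directed.mean() / half_n),
    )


def hbond_angle_sweep(
    traj: Trajectory,
    cutoffs=tuple(range(10, 61, 10)),
    oo_cutoff: float = 3.5,
) -> np.ndarray:
    """Mean bonds per molecule for each angular half-width (degrees).

    Counts are non-decreasing in the cutoff (larger windows accept a
    superset of geometries).  The pair geometry is evaluated once per frame
    and re-thresholded per cutoff.
    """
    cutoffs = np.asarray(cutoffs, dtype=float)
    totals = np.zeros(cutoffs.size)
    n_mol = 0
    for f in range(traj.n_frames):
        dist, dev_i, dev_j, n_mol = _pair_geometry(traj, f)
        close = dist < oo_cutoff
        min_dev = np.minimum(dev_i, dev_j)[close]
        for k, c in enumerate(cutoffs):
            totals[k] += np.count_nonzero(min_dev <= c)
    return totals / traj.n_frames / (n_mol / 2.0)


def rdf_first_minimum(rdf: RDFResult, min_peak_height: float = 0.5) -> float:
    """Locate the first minimum after the first peak of g(r).

    This is how a distance cutoff (e.g. the O–O hydrogen-bond cutoff) is
    derived from the pair structure instead of being hard-coded.
    """
    peaks, _ = find_peaks(rdf.g, height=min_peak_height)
    if peaks.size == 0:
        raise ValueError("no peak found in g(r)")
    p0 = peaks[0]
    minima, _ = find_peaks(-rdf.g[p0:])
    if minima.size == 0:
        raise ValueError("no minimum found after the first peak of g(r)")
    return float(rdf.r[p0 + minima[0]])
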