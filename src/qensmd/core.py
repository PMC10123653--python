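"""Core domain types, physical constants, and unit conversions.

Coordinates are Cartesian angstroms, times picoseconds, energies meV
(spectra are also quoted in micro-eV where conventional).  Self-diffusion
coefficients are reported in units of 1e-10 m^2/s to match the scale on
which liquid-state QENS results are tabulated.  Trajectories are stored
unwrapped internally; wrapping happens only at I/O boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = [
    "CONSTANTS",
    "AtomRecord",
    "PhysicalConstants",
    "SimulationCell",
    "Trajectory",
    "DEFAULT_B_INC",
    "UnwrapError",
    "validate_trajectory",
    "unwrap_periodic",
    "wrap_positions",
]

#: Default incoherent scattering lengths in fm.  1H dominates the incoherent
#: cross-section of organic liquids; 12C and 16O are spin-zero and contribute
#: essentially nothing, so their incoherent lengths default to zero.  The
#: table is overridable per topology.
DEFAULT_B_INC: dict[str, float] = {"H": 25.274, "C": 0.0, "O": 0.0}

#: Standard atomic masses (amu) for the packaged templates.
ATOMIC_MASS: dict[str, float] = {"H": 1.008, "C": 12.011, "O": 15.999}


@dataclass(frozen=True)
class PhysicalConstants:
    """Fixed physical constants; all unit conversions route through here.

    hbar is in meV·ps, the natural unit pair for ps-resolved trajectories
    and micro-eV-scale spectra; R_gas in J/(mol K); ``msd_slope_to_SI``
    converts an MSD slope in Å²/ps to m²/s.
    """

    hbar: float = 0.6582119569          # meV ps
    R_gas: float = 8.314462618          # J / (mol K)
    msd_slope_to_SI: float = 1.0e-8     # (Å²/ps) -> m²/s


CONSTANTS = PhysicalConstants()


@dataclass(frozen=True)
class AtomRecord:
    """Per-atom metadata: identity, scattering weight and molecule grouping.

    ``b_inc`` is the incoherent scattering length in fm; it enters all
    neutron-weighted averages as b_inc².  ``site_label`` distinguishes
    chemically different sites of the same element (hydroxyl-H, methyl-H,
    ring-C, ...).
    """

    atom_id: int
    element: str
    site_label: str
    mass: float
    b_inc: float
    molecule_id: int

    def __post_init__(self) -> None:
        if self.b_inc < 0:
            raise ValueError(f"atom {self.atom_id}: b_inc must be >= 0, got {self.b_inc}")
        if self.mass <= 0:
            raise ValueError(f"atom {self.atom_id}: mass must be > 0, got {self.mass}")


@dataclass(frozen=True)
class SimulationCell:
    """Orthorhombic periodic cell with edge lengths in Å."""

    edge_lengths: tuple[float, float, float]
    periodic: bool = True

    def __post_init__(self) -> None:
        edges = tuple(float(e) for e in self.edge_lengths)
        object.__setattr__(self, "edge_lengths", edges)
        if self.periodic and any(e <= 0 for e in edges):
            raise ValueError(f"periodic cell requires positive edges, got {edges}")

    @property
    def edges(self) -> np.ndarray:
        return np.asarray(self.edge_lengths, dtype=float)

    @property
    def volume(self) -> float:
        return float(np.prod(self.edges))


@dataclass
class Trajectory:
    """Time-ordered particle positions in a periodic cell.

    positions has shape (n_frames, n_atoms, 3) in Å; frames are separated
    by ``frame_interval`` ps.  ``temperature_label`` is bookkeeping metadata
    (the nominal thermostat temperature in K), not used in any computation.
    """

    positions: np.ndarray
    frame_interval: float
    cell: SimulationCell
    atoms: tuple[AtomRecord, ...]
    temperature_label: float | None = None

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.atoms = tuple(self.atoms)

    @property
    def n_frames(self) -> int:
        return int(self.positions.shape[0])

    @property
    def n_atoms(self) -> int:
        return int(self.positions.shape[1])

    @property
    def times(self) -> np.ndarray:
        """Frame times in ps, starting at 0."""
        return np.arange(self.n_frames) * self.frame_interval

    def b_inc_weights(self) -> np.ndarray:
        """Per-atom weights proportional to b_inc², normalized to sum 1."""
        b = np.array([a.b_inc for a in self.atoms], dtype=float)
        w = b * b
        total = w.sum()
        if total <= 0:
            raise ValueError("all incoherent scattering lengths are zero")
        return w / total

    def molecule_ids(self) -> np.ndarray:
        return np.array([a.molecule_id for a in self.atoms], dtype=int)

    def center_of_mass_trajectory(self) -> "Trajectory":
        """Reduce to one pseudo-atom per molecule at the molecular center of mass."""
        mol_ids = self.molecule_ids()
        unique = np.unique(mol_ids)
        masses = np.array([a.mass for a in self.atoms], dtype=float)
        com = np.empty((self.n_frames, unique.size, 3))
        records = []
        for j, m in enumerate(unique):
            sel = mol_ids == m
            w = masses[sel] / masses[sel].sum()
            com[:, j, :] = np.einsum("fak,a->fk", self.positions[:, sel, :], w)
            records.append(
                AtomRecord(
                    atom_id=j,
                    element="X",
                    site_label="com",
                    mass=float(masses[sel].sum()),
                    b_inc=1.0,
                    molecule_id=int(m),
                )
            )
        return Trajectory(
            positions=com,
            frame_interval=self.frame_interval,
            cell=self.cell,
            atoms=tuple(records),
            temperature_label=self.temperature_label,
        )


class UnwrapError(ValueError):
    """Raised when periodic unwrapping is ambiguous (displacement > half box)."""


def validate_trajectory(traj: Trajectory) -> list[str]:
    """Check Trajectory invariants; return a list of violation descriptions.

    Validation never raises: an empty list means the trajectory is
    well-formed.  Each violation names the offending frame or field.
    """
    violations: list[str] = []
    pos = np.asarray(traj.positions)
    if pos.ndim != 3 or pos.shape[2] != 3:
        violations.append(
            f"positions must have shape (n_frames, n_atoms, 3); got {pos.shape}"
        )
        return violations
    if traj.n_frames < 2:
        violations.append(f"n_frames must be >= 2; got {traj.n_frames}")
    if not traj.frame_interval > 0:
        violations.append(f"frame_interval must be > 0; got {traj.frame_interval}")
    if len(traj.atoms) != traj.n_atoms:
        violations.append(
            f"atom record count {len(traj.atoms)} != position atom count {traj.n_atoms}"
        )
    for f in range(traj.n_frames):
        if not np.isfinite(pos[f]).all():
            bad = np.argwhere(~np.isfinite(pos[f]))[0]
            violations.append(f"frame {f}: non-finite coordinate at atom {bad[0]}")
    if traj.cell.periodic and any(e <= 0 for e in traj.cell.edge_lengths):
        violations.append(f"periodic cell has non-positive edge: {traj.cell.edge_lengths}")
    return violations


def _frame_atom_count_violations(frames: Sequence[np.ndarray]) -> list[str]:
    """Report frames whose atom count differs from frame 0 (pre-stacking check)."""
    if not frames:
        return ["no frames"]
    n0 = len(frames[0])
    return [
        f"frame {i}: atom count {len(f)} != {n0}"
        for i, f in enumerate(frames)
        if len(f) != n0
    ]


def wrap_positions(positions: np.ndarray, cell: SimulationCell) -> np.ndarray:
    """Wrap coordinates into [0, L) along each periodic axis."""
    if not cell.periodic:
        return np.array(positions, dtype=float)
    return np.mod(positions, cell.edges)


def unwrap_periodic(traj: Trajectory) -> Trajectory:
    """Remove minimum-image jumps so positions are continuous in time.

    Applies the minimum-image convention to successive frame-to-frame
    displacements and accumulates them.  Requires every per-frame
    displacement to be smaller than half the smallest cell edge; larger
    displacements make the unwrap ambiguous and raise :class:`UnwrapError`.
    Re-wrapping the result modulo the cell reproduces the input.
    """
    if not traj.cell.periodic:
        return traj
    edges = traj.cell.edges
    pos = traj.positions
    diffs = np.diff(pos, axis=0)
    shifts = np.round(diffs / edges)
    corrected = diffs - shifts * edges
    limit = edges.min() / 2.0
    norms = np.linalg.norm(corrected, axis=2)
    if norms.size and norms.max() >= limit:
        f, a = np.unravel_index(np.argmax(norms), norms.shape)
        raise UnwrapError(
            f"displacement {norms[f, a]:.3f} Å of atom {a} between frames "
            f"{f} and {f + 1} exceeds half the smallest cell edge ({limit:.3f} Å); "
            "unwrap is ambiguous"
        )
    unwrapped = np.concatenate(
        [pos[:1], pos[:1] + np.cumsum(corrected, axis=0)], axis=0
    )
    return replace(traj, positions=unwrapped)
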