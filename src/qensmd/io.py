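"""Trajectory and spectrum I/O.

Extended XYZ (with ``Lattice=...`` and ``Time=...`` comment metadata) is the
canonical interchange format; the DL_POLY HISTORY positions-only dialect is
supported read-only so engine outputs can be ingested.  Readers reject
malformed input rather than silently repairing it, and every error names the
offending frame or line.

Coordinates in files may be wrapped into the cell; readers never unwrap
implicitly — pass the result through :func:`qensmd.core.unwrap_periodic`.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .core import ATOMIC_MASS, DEFAULT_B_INC, AtomRecord, SimulationCell, Trajectory

__all__ = [
    "SpectrumTable",
    "read_xyz",
    "write_xyz",
    "read_dlpoly_history",
    "read_spectrum_table",
    "write_spectrum_table",
    "read_spectrum_h5",
    "write_spectrum_h5",
]


@dataclass
class SpectrumTable:
    """S(Q, E) on explicit Q (Å⁻¹) and energy-transfer (meV) grids.

    ``intensity`` has shape (n_q, n_energy) in 1/meV; ``uncertainty`` is
    optional with the same shape.
    """

    q: np.ndarray
    energy: np.ndarray
    intensity: np.ndarray
    uncertainty: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.q = np.atleast_1d(np.asarray(self.q, dtype=float))
        self.energy = np.asarray(self.energy, dtype=float)
        self.intensity = np.atleast_2d(np.asarray(self.intensity, dtype=float))
        if self.q.size == 0:
            raise ValueError("Q grid is empty")
        if np.any(np.diff(self.energy) <= 0):
            raise ValueError("energy grid must be strictly increasing")
        if self.intensity.shape != (self.q.size, self.energy.size):
            raise ValueError(
                f"intensity shape {self.intensity.shape} does not match "
                f"(n_q={self.q.size}, n_energy={self.energy.size})"
            )
        if self.uncertainty is not None:
            self.uncertainty = np.asarray(self.uncertainty, dtype=float)
            if self.uncertainty.shape != self.intensity.shape:
                raise ValueError("uncertainty shape mismatch")


# ---------------------------------------------------------------------------
# extended XYZ

_KV_RE = re.compile(r'(\w+)=(?:"([^"]*)"|(\S+))')


def _parse_comment(line: str) -> dict[str, str]:
    return {m.group(1): m.group(2) if m.group(2) is not None else m.group(3)
            for m in _KV_RE.finditer(line)}


def write_xyz(traj: Trajectory, path: str | Path) -> None:
    """Write an extended-XYZ file with lattice, time and per-atom metadata."""
    path = Path(path)
    e = traj.cell.edges
    lattice = f"{e[0]:.6f} 0.0 0.0 0.0 {e[1]:.6f} 0.0 0.0 0.0 {e[2]:.6f}"
    props = "species:S:1:pos:R:3:site_label:S:1:molecule_id:I:1:mass:R:1:b_inc:R:1"
    with path.open("w") as fh:
        for f in range(traj.n_frames):
            fh.write(f"{traj.n_atoms}\n")
            fh.write(
                f'Lattice="{lattice}" Properties={props} '
                f"Time={f * traj.frame_interval:.6f}\n"
            )
            for a, rec in enumerate(traj.atoms):
                x, y, z = traj.positions[f, a]
                fh.write(
                    f"{rec.element} {x:.6f} {y:.6f} {z:.6f} "
                    f"{rec.site_label} {rec.molecule_id} {rec.mass:.6f} {rec.b_inc:.6f}\n"
                )


def read_xyz(path: str | Path, periodic: bool = True) -> Trajectory:
    """Read an extended-XYZ trajectory.

    Requires a ``Lattice`` comment entry when ``periodic``; atom count and
    ordering must be constant across frames.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    i, frame_idx = 0, 0
    frames: list[np.ndarray] = []
    times: list[float] = []
    cell: SimulationCell | None = None
    atoms: tuple[AtomRecord, ...] | None = None
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n = int(lines[i].strip())
        except ValueError as exc:
            raise ValueError(
                f"frame {frame_idx}: malformed atom-count header at line {i + 1}: "
                f"{lines[i]!r}"
            ) from exc
        if i + 2 + n > len(lines):
            raise ValueError(f"frame {frame_idx}: truncated (expected {n} atoms)")
        meta = _parse_comment(lines[i + 1])
        if "Lattice" in meta:
            mat = np.fromstring(meta["Lattice"], sep=" ").reshape(3, 3)
            if np.any(np.abs(mat - np.diag(np.diag(mat))) > 1e-9):
                raise ValueError(f"frame {frame_idx}: non-orthorhombic lattice")
            frame_cell = SimulationCell(tuple(np.diag(mat)), periodic=periodic)
        elif periodic:
            raise ValueError(f"frame {frame_idx}: missing Lattice entry for periodic trajectory")
        else:
            frame_cell = SimulationCell((1.0, 1.0, 1.0), periodic=False)
        if cell is None:
            cell = frame_cell
        if "Time" in meta:
            times.append(float(meta["Time"]))
        pos = np.empty((n, 3))
        recs: list[AtomRecord] = []
        for a in range(n):
            parts = lines[i + 2 + a].split()
            if len(parts) < 4:
                raise ValueError(
                    f"frame {frame_idx}: malformed atom line {i + 3 + a}: "
                    f"{lines[i + 2 + a]!r}"
                )
            element = parts[0]
            pos[a] = [float(p) for p in parts[1:4]]
            if atoms is None:
                site = parts[4] if len(parts) > 4 else element
                mol = int(parts[5]) if len(parts) > 5 else 0
                mass = float(parts[6]) if len(parts) > 6 else ATOMIC_MASS.get(element, 1.0)
                binc = float(parts[7]) if len(parts) > 7 else DEFAULT_B_INC.get(element, 0.0)
                recs.append(
                    AtomRecord(atom_id=a, element=element, site_label=site,
                               mass=mass, b_inc=binc, molecule_id=mol)
                )
        if atoms is None:
            atoms = tuple(recs)
        elif n != len(atoms):
            raise ValueError(
                f"frame {frame_idx}: atom count {n} differs from frame 0 count {len(atoms)}"
            )
        frames.append(pos)
        i += 2 + n
        frame_idx += 1
    if not frames or cell is None or atoms is None:
        raise ValueError(f"{path}: no frames found")
    if len(times) >= 2:
        interval = float(times[1] - times[0])
        if interval <= 0:
            raise ValueError("frame times are not strictly increasing")
    else:
        interval = 1.0
    return Trajectory(
        positions=np.stack(frames), frame_interval=interval, cell=cell, atoms=atoms
    )


# ---------------------------------------------------------------------------
# DL_POLY HISTORY (positions-only dialect)


def read_dlpoly_history(
    path: str | Path, atoms_per_molecule: int | None = None
) -> Trajectory:
    """Read a DL_POLY HISTORY file with trajectory key 0 (positions only).

    Orthorhombic cell records are required; element symbols and site labels
    are inferred from the atom-name prefix (e.g. ``HW1`` → element H, site
    ``HW1``).  ``atoms_per_molecule`` optionally groups consecutive atoms
    into molecules; otherwise every atom is its own molecule.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    if len(lines) < 2:
        raise ValueError(f"{path}: not a HISTORY file (fewer than 2 lines)")
    header_parts = lines[1].split()
    if len(header_parts) < 3:
        raise ValueError(f"{path}: malformed HISTORY control line: {lines[1]!r}")
    keytrj, imcon, natms = (int(p) for p in header_parts[:3])
    if keytrj != 0:
        raise ValueError(
            f"{path}: unsupported trajectory key {keytrj} (only key 0, positions only)"
        )
    if imcon not in (1, 2):
        raise ValueError(f"{path}: unsupported periodic boundary key imcon={imcon}")

    i = 2
    frames: list[np.ndarray] = []
    times: list[float] = []
    cell: SimulationCell | None = None
    names: list[str] | None = None
    frame_idx = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        parts = lines[i].split()
        if parts[0] != "timestep":
            raise ValueError(f"frame {frame_idx}: expected 'timestep' record at line {i + 1}")
        nstep = int(parts[1])
        tstep = float(parts[5]) if len(parts) > 5 else 1.0
        times.append(nstep * tstep)
        mat = np.array([[float(v) for v in lines[i + 1 + r].split()] for r in range(3)])
        if np.any(np.abs(mat - np.diag(np.diag(mat))) > 1e-6):
            raise ValueError(f"frame {frame_idx}: non-orthorhombic cell matrix")
        if cell is None:
            cell = SimulationCell(tuple(np.diag(mat)))
        i += 4
        pos = np.empty((natms, 3))
        frame_names: list[str] = []
        for a in range(natms):
            name_line = lines[i].split()
            frame_names.append(name_line[0])
            pos[a] = [float(v) for v in lines[i + 1].split()[:3]]
            i += 2
        if names is None:
            names = frame_names
        frames.append(pos)
        frame_idx += 1
    if not frames or cell is None or names is None:
        raise ValueError(f"{path}: no frames found")

    atoms = []
    for a, name in enumerate(names):
        element = name[0].upper()
        mol = a // atoms_per_molecule if atoms_per_molecule else a
        atoms.append(
            AtomRecord(
                atom_id=a, element=element, site_label=name,
                mass=ATOMIC_MASS.get(element, 1.0),
                b_inc=DEFAULT_B_INC.get(element, 0.0), molecule_id=mol,
            )
        )
    if len(times) >= 2 and times[1] - times[0] > 0:
        interval = float(times[1] - times[0])
    else:
        interval = 1.0
    return Trajectory(
        positions=np.stack(frames), frame_interval=interval, cell=cell,
        atoms=tuple(atoms),
    )


# ---------------------------------------------------------------------------
# spectrum tables


def write_spectrum_table(spec: SpectrumTable, path: str | Path) -> None:
    """Write a delimited spectrum table (energies in meV down the rows, one
    intensity column per Q), lossless at 8 significant digits."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("# qensmd spectrum table\n")
        fh.write("# units: energy=meV q=1/angstrom intensity=1/meV\n")
        fh.write("# q: " + " ".join(f"{q:.8g}" for q in spec.q) + "\n")
        if spec.uncertainty is not None:
            fh.write("# uncertainty: present\n")
        cols = ["energy"] + [f"S_q{j}" for j in range(spec.q.size)]
        if spec.uncertainty is not None:
            cols += [f"dS_q{j}" for j in range(spec.q.size)]
        fh.write("\t".join(cols) + "\n")
        for k, e in enumerate(spec.energy):
            row = [f"{e:.8e}"] + [f"{v:.8e}" for v in spec.intensity[:, k]]
            if spec.uncertainty is not None:
                row += [f"{v:.8e}" for v in spec.uncertainty[:, k]]
            fh.write("\t".join(row) + "\n")


def read_spectrum_table(path: str | Path) -> SpectrumTable:
    path = Path(path)
    lines = path.read_text().splitlines()
    header = [l for l in lines if l.startswith("#")]
    if not any("units:" in l for l in header):
        raise ValueError(f"{path}: missing unit header line ('# units: ...')")
    q_line = next((l for l in header if l.startswith("# q:")), None)
    if q_line is None:
        raise ValueError(f"{path}: missing '# q:' header line")
    q = np.fromstring(q_line.split(":", 1)[1], sep=" ")
    has_unc = any("uncertainty: present" in l for l in header)
    data_lines = [l for l in lines if l and not l.startswith("#")]
    data = np.array(
        [[float(v) for v in l.split()] for l in data_lines[1:]]  # skip column header
    )
    energy = data[:, 0]
    if np.any(np.diff(energy) <= 0):
        raise ValueError(f"{path}: energy grid not strictly increasing")
    nq = q.size
    intensity = data[:, 1 : 1 + nq].T
    unc = data[:, 1 + nq : 1 + 2 * nq].T if has_unc else None
    return SpectrumTable(q=q, energy=energy, intensity=intensity, uncertainty=unc)


def write_spectrum_h5(spec: SpectrumTable, path: str | Path) -> None:
    """HDF5 mirror of :class:`SpectrumTable` for large outputs."""
    import h5py

    with h5py.File(path, "w") as fh:
        fh.create_dataset("q", data=spec.q)
        fh.create_dataset("energy", data=spec.energy)
        fh.create_dataset("intensity", data=spec.intensity)
        if spec.uncertainty is not None:
            fh.create_dataset("uncertainty", data=spec.uncertainty)
        fh.attrs["energy_unit"] = "meV"
        fh.attrs["q_unit"] = "1/angstrom"


def read_spectrum_h5(path: str | Path) -> SpectrumTable:
    import h5py

    with h5py.File(path, "r") as fh:
        return SpectrumTable(
            q=fh["q"][...],
            energy=fh["energy"][...],
            intensity=fh["intensity"][...],
            uncertainty=fh["uncertainty"][...] if "uncertainty" in fh else None,
        )
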