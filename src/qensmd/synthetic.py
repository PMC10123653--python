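"""Synthetic trajectory generators with known ground-truth dynamics.

The generators emulate the study conditions every downstream stage is
exercised against: a few hundred rigid p-cresol-like molecules in a ~40 Å
cubic periodic box, positions sampled every picosecond for nanoseconds, at
liquid-state temperatures.  Translation is a renewal jump process
(exponential residence times, Gaussian jump lengths — the generative
counterpart of Hall–Ross jump diffusion), rotation is isotropic rotational
Brownian motion, and the two are independent.  For this process the
incoherent ISF of the molecular center has the closed form

    F(Q, t) = exp(-(t/tau) * (1 - exp(-Q^2 sigma^2 / 2)))

i.e. a Lorentzian line of HWHM (hbar/tau)(1 - exp(-Q^2 sigma^2 / 2)) — the
Hall–Ross law with jump-length parameter d = sigma — which makes full-chain
parameter recovery exactly testable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq
from scipy.spatial.transform import Rotation

from .core import ATOMIC_MASS, DEFAULT_B_INC, AtomRecord, SimulationCell, Trajectory

__all__ = [
    "MolecularTemplate",
    "JumpRotSpec",
    "HBondFixture",
    "p_cresol_template",
    "generate_jump_rotation_trajectory",
    "generate_brownian_trajectory",
    "plant_hbond_configuration",
]


@dataclass(frozen=True)
class TemplateSite:
    element: str
    site_label: str


@dataclass(frozen=True)
class MolecularTemplate:
    """Rigid molecular geometry: site coordinates relative to the center of mass."""

    coords: np.ndarray          # (n_sites, 3), Å, COM at origin
    sites: tuple[TemplateSite, ...]

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float)
        masses = np.array([ATOMIC_MASS[s.element] for s in self.sites])
        com = masses @ coords / masses.sum()
        coords = coords - com
        object.__setattr__(self, "coords", coords)
        if coords.shape[0] != len(self.sites):
            raise ValueError("coords/sites length mismatch")

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def atom_records(self, molecule_id: int, first_atom_id: int) -> list[AtomRecord]:
        return [
            AtomRecord(
                atom_id=first_atom_id + i,
                element=s.element,
                site_label=s.site_label,
                mass=ATOMIC_MASS[s.element],
                b_inc=DEFAULT_B_INC[s.element],
                molecule_id=molecule_id,
            )
            for i, s in enumerate(self.sites)
        ]

    def site_index(self, label: str) -> int:
        for i, s in enumerate(self.sites):
            if s.site_label == label:
                return i
        raise KeyError(label)


def p_cresol_template() -> MolecularTemplate:
    """Idealized rigid p-cresol (4-methylphenol, C7H8O), 16 atoms.

    Planar aromatic ring of radius 1.397 Å in the xy plane; hydroxyl group
    para to the methyl group, giving a heavy-atom O-to-methyl-C span of
    ~5.7 Å.  Bond lengths are standard idealized values (C-C aromatic 1.397,
    C-H 1.083, C-O 1.364, O-H 0.96, C-CH3 1.510, methyl C-H 1.09 Å).
    """
    r_ring = 1.397
    coords: list[np.ndarray] = []
    sites: list[TemplateSite] = []

    def add(xyz, element, label):
        coords.append(np.asarray(xyz, dtype=float))
        sites.append(TemplateSite(element, label))

    ring_angles = np.deg2rad([0, 60, 120, 180, 240, 300])
    for k, th in enumerate(ring_angles):
        add([r_ring * np.cos(th), r_ring * np.sin(th), 0.0], "C", "ring-C")
    # ring hydrogens on C2, C3, C5, C6 (C1 bears OH, C4 bears CH3)
    for th in np.deg2rad([60, 120, 240, 300]):
        rh = r_ring + 1.083
        add([rh * np.cos(th), rh * np.sin(th), 0.0], "H", "ring-H")
    # hydroxyl on C1 (+x): C-O 1.364, O-H 0.96 at 109 deg from O->C direction
    o_pos = np.array([r_ring + 1.364, 0.0, 0.0])
    add(o_pos, "O", "hydroxyl-O")
    th_oh = np.deg2rad(180.0 - 109.0)
    add(o_pos + 0.96 * np.array([np.cos(th_oh), np.sin(th_oh), 0.0]), "H", "hydroxyl-H")
    # methyl on C4 (-x): C-C 1.510, tetrahedral hydrogens
    c7 = np.array([-(r_ring + 1.510), 0.0, 0.0])
    add(c7, "C", "methyl-C")
    cos_t, sin_t = np.cos(np.deg2rad(180 - 109.47)), np.sin(np.deg2rad(180 - 109.47))
    for phi in np.deg2rad([0.0, 120.0, 240.0]):
        direction = np.array([-cos_t, sin_t * np.cos(phi), sin_t * np.sin(phi)])
        add(c7 + 1.09 * direction, "H", "methyl-H")

    return MolecularTemplate(coords=np.array(coords), sites=tuple(sites))


@dataclass(frozen=True)
class JumpRotSpec:
    """Ground-truth parameters for the jump-rotation generator.

    tau: mean residence time between center-of-mass jumps, ps.
    sigma_jump: per-Cartesian-component rms jump length, Å (the Hall–Ross
        jump-length parameter d of the generated dynamics).
    D_rot: rotational diffusion coefficient, s^-1.
    vib_amp: rms amplitude of the uncorrelated in-cage jitter, Å.  This
        emulates fast vibrations outside the instrument window and produces
        the flat spectral background.  Default 0.2 Å.
    Defaults mirror the emulated study setup: 384 molecules, 40 Å cube,
    1 ps sampling, 5000 frames (5 ns production).
    """

    tau: float
    sigma_jump: float
    D_rot: float
    n_molecules: int = 384
    cell_edge: float = 40.0
    n_frames: int = 5000
    frame_interval: float = 1.0
    vib_amp: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise ValueError(f"tau must be > 0, got {self.tau}")
        for name in ("sigma_jump", "D_rot", "vib_amp"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_molecules < 1 or self.n_frames < 2:
            raise ValueError("need at least 1 molecule and 2 frames")


def _brownian_rotations(
    rng: np.random.Generator, n_frames: int, d_rot_ps: float, dt: float
) -> np.ndarray:
    """Cumulative orientation matrices for isotropic rotational diffusion.

    Successive small random rotations about space-fixed axes, with rotation
    vector variance 2*D_rot*dt per axis and per frame.  Each frame step is
    internally substepped so the per-step angle variance stays below
    0.05 rad², keeping the small-angle composition in the regime where it
    converges to rotational Brownian motion even for fast rotors.
    """
    var = 2.0 * d_rot_ps * dt
    n_sub = max(1, int(np.ceil(var / 0.05)))
    std = np.sqrt(var / n_sub)
    mats = np.empty((n_frames, 3, 3))
    current = Rotation.identity()
    mats[0] = current.as_matrix()
    for f in range(1, n_frames):
        rotvecs = rng.normal(0.0, std, size=(n_sub, 3))
        for v in rotvecs:
            current = Rotation.from_rotvec(v) * current
        mats[f] = current.as_matrix()
    return mats


def generate_jump_rotation_trajectory(
    spec: JumpRotSpec,
    template: MolecularTemplate,
    return_events: bool = False,
) -> Trajectory | tuple[Trajectory, list[np.ndarray]]:
    """Generate a rigid-molecule trajectory with jump translation and rotational diffusion.

    Each molecule's center of mass performs a renewal process: residence
    times drawn exponential(mean=tau); at each jump the displacement is an
    isotropic Gaussian with per-component standard deviation sigma_jump.
    Between jumps the center jitters around its equilibrium position with
    uncorrelated Gaussian noise of rms vib_amp per component.  Orientations
    perform independent rotational Brownian motion with coefficient D_rot.
    Molecules do not interact.  Fully determined by ``spec.seed``.

    With ``return_events`` the per-molecule arrays of jump times (ps) are
    returned alongside, so waiting-time statistics can be checked against
    the generator's own event log rather than re-inferred from positions.
    """
    rng = np.random.default_rng(spec.seed)
    dt = spec.frame_interval
    n_f, n_m = spec.n_frames, spec.n_molecules
    edges = np.array([spec.cell_edge] * 3)

    rms_frame = spec.sigma_jump * np.sqrt(3.0 * dt / spec.tau)
    if rms_frame > spec.cell_edge / 2.0:
        raise ValueError(
            f"expected per-frame jump displacement {rms_frame:.2f} Å exceeds "
            f"half the cell edge {spec.cell_edge / 2.0:.2f} Å"
        )

    d_rot_ps = spec.D_rot * 1e-12  # s^-1 -> ps^-1
    total_time = (n_f - 1) * dt
    times = np.arange(n_f) * dt

    positions = np.empty((n_f, n_m * template.n_sites, 3))
    atoms: list[AtomRecord] = []
    events: list[np.ndarray] = []

    for m in range(n_m):
        start = rng.uniform(0.0, spec.cell_edge, size=3)
        # renewal jump times and displacements
        jump_times: list[float] = []
        t = rng.exponential(spec.tau)
        while t <= total_time:
            jump_times.append(t)
            t += rng.exponential(spec.tau)
        jt = np.asarray(jump_times)
        events.append(jt)
        jumps = rng.normal(0.0, spec.sigma_jump, size=(jt.size, 3))
        # equilibrium COM at each frame: start + sum of jumps before that time
        n_before = np.searchsorted(jt, times, side="right")
        cum = np.concatenate([np.zeros((1, 3)), np.cumsum(jumps, axis=0)], axis=0)
        eq = start + cum[n_before]
        com = eq + rng.normal(0.0, spec.vib_amp, size=(n_f, 3))

        r0 = Rotation.random(random_state=rng).as_matrix()  # isotropic initial ensemble
        if d_rot_ps > 0:
            rot = _brownian_rotations(rng, n_f, d_rot_ps, dt) @ r0
        else:
            rot = np.broadcast_to(r0, (n_f, 3, 3))
        body = template.coords  # (s, 3)
        positions[:, m * template.n_sites : (m + 1) * template.n_sites, :] = (
            com[:, None, :] + np.einsum("fij,sj->fsi", rot, body)
        )
        atoms.extend(template.atom_records(molecule_id=m, first_atom_id=m * template.n_sites))

    traj = Trajectory(
        positions=positions,
        frame_interval=dt,
        cell=SimulationCell(tuple(edges)),
        atoms=tuple(atoms),
    )
    if return_events:
        return traj, events
    return traj


def generate_brownian_trajectory(
    n_particles: int,
    D_target: float,
    n_frames: int,
    frame_interval: float = 1.0,
    cell: SimulationCell | None = None,
    seed: int = 0,
) -> Trajectory:
    """Free Brownian point scatterers: the analytic oracle for MSD and ISF tests.

    ``D_target`` is in m²/s.  Increments are independent Gaussians with
    per-component variance 2*D*dt, so MSD(t) = 6 D t exactly in expectation
    and F(Q, t) = exp(-D Q² t).
    """
    if D_target < 0:
        raise ValueError(f"D_target must be >= 0, got {D_target}")
    if cell is None:
        cell = SimulationCell((40.0, 40.0, 40.0))
    rng = np.random.default_rng(seed)
    d_ps = D_target / 1e-8  # m²/s -> Å²/ps
    std = np.sqrt(2.0 * d_ps * frame_interval)
    start = rng.uniform(0.0, min(cell.edge_lengths), size=(1, n_particles, 3))
    steps = rng.normal(0.0, std, size=(n_frames - 1, n_particles, 3))
    positions = np.concatenate([start, start + np.cumsum(steps, axis=0)], axis=0)
    atoms = tuple(
        AtomRecord(
            atom_id=i, element="H", site_label="tracer", mass=1.008,
            b_inc=DEFAULT_B_INC["H"], molecule_id=i,
        )
        for i in range(n_particles)
    )
    return Trajectory(
        positions=positions, frame_interval=frame_interval, cell=cell, atoms=atoms
    )


@dataclass(frozen=True)
class HBondFixture:
    """Single-frame configuration with a known number of planted hydrogen bonds."""

    trajectory: Trajectory
    planted_bond_count: int


def _donor_h_direction(d_oo: float, angle_deg: float, r_oh: float = 0.96) -> np.ndarray:
    """In the donor frame (donor O at origin, acceptor O at (d,0,0)), the unit
    direction from the donor O to its hydroxyl H such that the O-H-O angle at
    the hydrogen equals ``angle_deg``."""

    def angle_at_h(phi: float) -> float:
        h = r_oh * np.array([np.cos(phi), np.sin(phi), 0.0])
        v1 = -h
        v2 = np.array([d_oo, 0.0, 0.0]) - h
        c = v1 @ v2 / (np.linalg.norm(v1) * np.linalg.norm(v2))
        return np.degrees(np.arccos(np.clip(c, -1, 1)))

    phi = brentq(lambda p: angle_at_h(p) - angle_deg, 1e-6, np.pi / 2)
    return np.array([np.cos(phi), np.sin(phi), 0.0])


def _place_molecule(
    template: MolecularTemplate,
    o_target: np.ndarray,
    oh_dir: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Rigid placement of the template with its hydroxyl O at ``o_target`` and
    its O->H bond along ``oh_dir`` (random spin about that axis)."""
    i_o = template.site_index("hydroxyl-O")
    i_h = template.site_index("hydroxyl-H")
    src = template.coords[i_h] - template.coords[i_o]
    src = src / np.linalg.norm(src)
    tgt = oh_dir / np.linalg.norm(oh_dir)
    # rotation taking src to tgt, composed with a random spin about src first
    spin = Rotation.from_rotvec(src * rng.uniform(0, 2 * np.pi))
    v = np.cross(src, tgt)
    c = float(src @ tgt)
    if np.linalg.norm(v) < 1e-12:
        align = Rotation.identity() if c > 0 else Rotation.from_rotvec(
            np.pi * _any_perpendicular(src)
        )
    else:
        axis = v / np.linalg.norm(v)
        align = Rotation.from_rotvec(axis * np.arccos(np.clip(c, -1, 1)))
    rot = (align * spin).as_matrix()
    placed = template.coords @ rot.T
    return placed + (o_target - placed[i_o])


def _any_perpendicular(u: np.ndarray) -> np.ndarray:
    v = np.array([1.0, 0.0, 0.0]) if abs(u[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    w = np.cross(u, v)
    return w / np.linalg.norm(w)


def plant_hbond_configuration(
    n_molecules: int,
    n_bonds: int,
    cell: SimulationCell | None = None,
    seed: int = 0,
    template: MolecularTemplate | None = None,
) -> HBondFixture:
    """Build a frame in which exactly ``n_bonds`` donor–acceptor pairs satisfy
    the geometric hydrogen-bond criteria (O···O < 3.5 Å, O-H-O within
    180° ± 20°) with margin, and every other intermolecular O pair is kept
    farther than 3.8 Å so no spurious bonds can form.

    Molecules are grouped into units (bonded dimers and singletons) whose
    hydroxyl oxygens sit on a jittered cubic grid; raises when the grid
    cannot hold all units inside the cell.
    """
    if 2 * n_bonds > n_molecules:
        raise ValueError(f"2*n_bonds={2 * n_bonds} exceeds n_molecules={n_molecules}")
    if cell is None:
        cell = SimulationCell((80.0, 80.0, 80.0))
    if template is None:
        template = p_cresol_template()
    rng = np.random.default_rng(seed)

    d_oo, angle = 2.9, 175.0
    # grid spacing: worst-case inter-unit O-O = spacing - d_oo - 2*jitter ≈ 4.5 Å,
    # comfortably beyond the 3.6 Å (criterion + margin) exclusion radius
    spacing = 8.5
    n_units = n_bonds + (n_molecules - 2 * n_bonds)
    k = int(min(cell.edge_lengths) // spacing)
    if k**3 < n_units:
        raise ValueError(
            f"cell of edge {min(cell.edge_lengths)} Å holds only {k ** 3} units at "
            f"{spacing} Å spacing; {n_units} required"
        )
    slots = np.array(
        [[i, j, l] for i in range(k) for j in range(k) for l in range(k)], dtype=float
    ) * spacing + spacing / 2.0
    rng.shuffle(slots)
    slots = slots[:n_units] + rng.uniform(-0.3, 0.3, size=(n_units, 3))

    frames: list[np.ndarray] = []
    atoms: list[AtomRecord] = []
    mol_id = 0

    def add_molecule(placed: np.ndarray) -> None:
        nonlocal mol_id
        frames.append(placed)
        atoms.extend(template.atom_records(mol_id, mol_id * template.n_sites))
        mol_id += 1

    for u in range(n_bonds):
        axis = _random_unit(rng)
        o1 = slots[u] - axis * d_oo / 2.0
        o2 = slots[u] + axis * d_oo / 2.0
        # donor H direction: rotate the in-plane solution into the pair frame
        local = _donor_h_direction(d_oo, angle)
        ex = axis
        ey = _any_perpendicular(ex)
        h_dir = local[0] * ex + local[1] * ey
        add_molecule(_place_molecule(template, o1, h_dir, rng))
        # acceptor: point its hydroxyl H away from the donor to keep geometry clean
        add_molecule(_place_molecule(template, o2, ex, rng))
    for u in range(n_bonds, n_units):
        add_molecule(_place_molecule(template, slots[u], _random_unit(rng), rng))

    positions = np.concatenate(frames, axis=0)[None, :, :]
    # count_hbonds needs >= 2 frames is not required; but Trajectory validation
    # wants n_frames >= 2 — duplicate the frame so the fixture is a valid clip.
    positions = np.repeat(positions, 2, axis=0)
    traj = Trajectory(
        positions=positions, frame_interval=1.0, cell=cell, atoms=tuple(atoms)
    )
    return HBondFixture(trajectory=traj, planted_bond_count=n_bonds)


def _random_unit(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)
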