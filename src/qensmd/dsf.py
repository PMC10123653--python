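"""Incoherent intermediate scattering function and dynamic structure factor.

F_inc(Q, t) is the b_inc²-weighted self-correlation of single-particle
displacements; for an isotropic system the powder average of
exp(iQ·Δr) is exactly sinc(Q|Δr|), which is used as the default kernel
(a seeded random-direction shell average is available as a cross-check).
S_inc(Q, ω) follows by a real cosine transform of the symmetrized,
classical (real) F, after multiplying in the instrument resolution in the
time domain: a Gaussian energy resolution of width σ_E is exactly the
factor exp(-σ_E² t² / 2ħ²).  The default resolution emulates an
IRIS-like backscattering spectrometer (Gaussian, fwhm 17.5 μeV) and the
default energy window is ±0.53 meV.

No detailed-balance factor is applied: classical trajectories give real,
symmetric F, and over a ±0.53 meV window at 340–390 K the quantum
asymmetry is below ~2%, smaller than the fitting uncertainties.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import CONSTANTS, Trajectory
from .io import SpectrumTable

__all__ = [
    "QGrid",
    "ISFSet",
    "ResolutionModel",
    "default_qgrid",
    "compute_incoherent_isf",
    "apply_resolution",
    "isf_to_dsf",
]

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass(frozen=True)
class QGrid:
    """Scattering-vector moduli in Å⁻¹, strictly increasing and positive."""

    moduli: tuple[float, ...]

    def __post_init__(self) -> None:
        m = tuple(float(q) for q in self.moduli)
        object.__setattr__(self, "moduli", m)
        arr = np.asarray(m)
        if arr.size == 0 or np.any(arr <= 0) or np.any(np.diff(arr) <= 0):
            raise ValueError(f"Q grid must be strictly increasing and > 0, got {m}")

    @property
    def values(self) -> np.ndarray:
        return np.asarray(self.moduli)


def default_qgrid() -> QGrid:
    """Q = 0.4–1.6 Å⁻¹ in steps of 0.2, the grid used for simulated spectra."""
    return QGrid(tuple(np.round(np.arange(0.4, 1.61, 0.2), 10)))


@dataclass(frozen=True)
class ResolutionModel:
    """Gaussian instrument resolution; fwhm in μeV (default 17.5)."""

    fwhm_ueV: float = 17.5

    def __post_init__(self) -> None:
        if self.fwhm_ueV <= 0:
            raise ValueError("resolution fwhm must be > 0")

    @property
    def sigma_meV(self) -> float:
        return self.fwhm_ueV * 1e-3 * _FWHM_TO_SIGMA


@dataclass
class ISFSet:
    """F(Q, t) on the trajectory lag grid; normalized so F(Q, 0) = 1."""

    q: np.ndarray               # Å⁻¹
    lag_times: np.ndarray       # ps, uniform, starting at 0
    f: np.ndarray               # (n_q, n_lag)
    normalized: bool = True
    resolution_applied: bool = False

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)
        self.lag_times = np.asarray(self.lag_times, dtype=float)
        self.f = np.asarray(self.f, dtype=float)
        if self.normalized:
            if not np.allclose(self.f[:, 0], 1.0, atol=1e-9):
                raise ValueError("normalized ISF must have F(Q, 0) = 1")
            if np.any(np.abs(self.f) > 1.0 + 1e-6):
                raise ValueError("normalized ISF must satisfy |F| <= 1")


def compute_incoherent_isf(
    traj: Trajectory,
    qgrid: QGrid | None = None,
    weighting: str = "b_inc",
    max_lag: float | None = None,
    origin_stride: int = 1,
    method: str = "sinc",
    n_directions: int = 64,
    seed: int = 0,
) -> ISFSet:
    """Powder-averaged incoherent ISF from an unwrapped trajectory.

    F(Q, Δ) = Σ_α w_α ⟨ sinc(Q |r_α(t+Δ) - r_α(t)|) ⟩ over atoms and time
    origins, with w_α ∝ b_inc,α² normalized to 1 (or unweighted molecular
    centers of mass with ``weighting="com"``).  ``max_lag`` defaults to
    min(n_frames/4 · Δt, 200 ps): the resolution damping makes longer lags
    irrelevant for instrument-scale spectra.  ``origin_stride`` subsamples
    time origins to trade statistics for speed.  ``method="shell"`` replaces
    the exact sinc kernel by an average over ``n_directions`` seeded random
    Q directions (cross-check mode).
    """
    if traj.n_frames < 2:
        raise ValueError("need >= 2 frames")
    if qgrid is None:
        qgrid = default_qgrid()
    qs = qgrid.values

    if weighting == "com":
        traj = traj.center_of_mass_trajectory()
        weights = np.full(traj.n_atoms, 1.0 / traj.n_atoms)
        pos = traj.positions
    elif weighting == "b_inc":
        weights = traj.b_inc_weights()
        sel = weights > 0
        weights = weights[sel] / weights[sel].sum()
        pos = traj.positions[:, sel, :]
    else:
        raise ValueError(f"unknown weighting {weighting!r}")

    n = traj.n_frames
    dt = traj.frame_interval
    if max_lag is None:
        max_lag = min(n / 4 * dt, 200.0)
    n_lag = min(n, int(round(max_lag / dt)) + 1)

    f = np.empty((qs.size, n_lag))
    f[:, 0] = 1.0
    if method == "shell":
        rng = np.random.default_rng(seed)
        dirs = rng.normal(size=(n_directions, 3))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    elif method != "sinc":
        raise ValueError(f"unknown method {method!r}")

    for d in range(1, n_lag):
        disp = pos[d:][::origin_stride] - pos[:-d][::origin_stride]  # (n_orig, n_at, 3)
        if method == "sinc":
            r = np.linalg.norm(disp, axis=2)
            for j, q in enumerate(qs):
                f[j, d] = np.sinc(q * r / np.pi).mean(axis=0) @ weights
        else:
            proj = np.einsum("oak,dk->oad", disp, dirs)
            for j, q in enumerate(qs):
                f[j, d] = np.cos(q * proj).mean(axis=(0, 2)) @ weights
    return ISFSet(q=qs, lag_times=np.arange(n_lag) * dt, f=f)


def apply_resolution(isf: ISFSet, res: ResolutionModel) -> ISFSet:
    """Multiply in the Gaussian energy resolution in the time domain.

    F'(Q, t) = F(Q, t) · exp(-σ_E² t² / 2ħ²) with σ_E = fwhm / (2√(2 ln 2)):
    the exact equivalent of convolving S(Q, ω) with the resolution Gaussian.
    """
    t = isf.lag_times
    damp = np.exp(-(res.sigma_meV**2) * t**2 / (2.0 * CONSTANTS.hbar**2))
    return ISFSet(
        q=isf.q,
        lag_times=t,
        f=isf.f * damp[None, :],
        normalized=isf.normalized,
        resolution_applied=True,
    )


def isf_to_dsf(
    isf: ISFSet,
    energy_window: float = 0.53,
    n_energy_points: int = 213,
    taper_fraction: float = 0.1,
    require_resolution: bool = True,
) -> SpectrumTable:
    """Cosine-transform the symmetrized F(Q, t) onto an energy grid (meV).

    S(Q, E) = (Δt / πħ) [F(0)/2 + Σ_k F(kΔt) w_k cos(E k Δt / ħ)] with a Hann
    taper w on the final ``taper_fraction`` of lags to suppress truncation
    ringing.  Normalization is such that ∫ S dE over the full line equals
    F(0); the integral actually captured inside the window is attached per Q
    as ``parseval_integral``.  Negative ringing is clamped at zero.  Raises
    if the energy window exceeds the Nyquist limit πħ/Δt, or if the
    resolution was not applied and not explicitly waived.
    """
    if require_resolution and not isf.resolution_applied:
        raise ValueError(
            "resolution not applied; call apply_resolution first or pass "
            "require_resolution=False to waive"
        )
    t = isf.lag_times
    dts = np.diff(t)
    if not np.allclose(dts, dts[0], rtol=1e-9):
        raise ValueError("lag grid must be uniform")
    dt = float(dts[0])
    e_nyq = np.pi * CONSTANTS.hbar / dt
    if energy_window > e_nyq + 1e-12:
        raise ValueError(
            f"energy window ±{energy_window} meV exceeds the Nyquist limit "
            f"±{e_nyq:.4f} meV for Δt = {dt} ps"
        )
    n_lag = t.size
    taper = np.ones(n_lag)
    k0 = int(np.floor((1.0 - taper_fraction) * (n_lag - 1)))
    if k0 < n_lag - 1:
        x = (np.arange(k0, n_lag) - k0) / (n_lag - 1 - k0)
        taper[k0:] = 0.5 * (1.0 + np.cos(np.pi * x))

    energy = np.linspace(-energy_window, energy_window, n_energy_points)
    phase = np.cos(np.outer(energy, t) / CONSTANTS.hbar)  # (nE, n_lag)
    coeff = isf.f * taper[None, :]
    coeff[:, 0] *= 0.5
    s = (dt / (np.pi * CONSTANTS.hbar)) * coeff @ phase.T  # (nq, nE)
    s = np.clip(s, 0.0, None)
    table = SpectrumTable(q=isf.q, energy=energy, intensity=s)
    table.parseval_integral = np.trapezoid(s, energy, axis=1)
    return table
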