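"""Mean squared displacements, Einstein-relation diffusion, Arrhenius fits.

The MSD is averaged over every time origin (the discrete counterpart of the
ensemble average) with an FFT-based correlator, and over atoms with weights
proportional to the squared incoherent scattering length — hydrogen carries
essentially the whole weight in organic liquids — or unweighted over
molecular centers of mass.  The self-diffusion coefficient follows from
MSD(t) → 6 D_s t over a lag window where log(MSD) vs log(t) is linear
(default 100–4000 ps), and activation energies from ordinary least squares
of ln(rate) on 1/T.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import CONSTANTS, Trajectory

__all__ = [
    "MSDCurve",
    "EinsteinFit",
    "ArrheniusResult",
    "compute_msd",
    "fit_einstein",
    "arrhenius_fit",
]


@dataclass
class MSDCurve:
    lag_times: np.ndarray   # ps, starting at 0
    msd: np.ndarray         # Å²
    weighting: str          # "b_inc" or "com"


@dataclass
class EinsteinFit:
    D_s: float              # m²/s
    window: tuple[float, float]  # ps
    loglog_slope: float
    diffusive: bool         # loglog slope within 0.2 of 1


@dataclass
class ArrheniusResult:
    E_a: float              # kJ/mol
    E_a_stderr: float       # kJ/mol, from fit residuals
    prefactor: float        # same units as input rates
    residuals: np.ndarray   # per-point residuals of ln(rate)


def _msd_fft(x: np.ndarray) -> np.ndarray:
    """Per-atom MSD over all time origins via the FFT correlator.

    x has shape (n_frames, n_atoms, 3); returns (n_frames, n_atoms).
    """
    n = x.shape[0]
    nfft = 1 << (2 * n - 1).bit_length()
    fx = np.fft.rfft(x, n=nfft, axis=0)
    acf = np.fft.irfft(fx * np.conj(fx), n=nfft, axis=0)[:n].sum(axis=2)
    counts = n - np.arange(n)  # valid origins per lag
    sq = (x * x).sum(axis=2)
    csum = np.cumsum(sq, axis=0)
    total = csum[-1]
    # S1(Δ) = sum_t [|r(t)|² + |r(t+Δ)|²] for t = 0..n-Δ-1
    s1 = np.empty_like(acf)
    s1[0] = 2.0 * total
    s1[1:] = csum[n - 2 :: -1] + (total - csum[: n - 1])
    return (s1 - 2.0 * acf) / counts[:, None]


def compute_msd(
    traj: Trajectory,
    weighting: str = "b_inc",
    max_lag: float | None = None,
    chunk: int = 256,
) -> MSDCurve:
    """Incoherent-weighted (or center-of-mass) MSD with all time origins.

    ``weighting="b_inc"`` averages atoms with weights ∝ b_inc² (atoms with
    zero incoherent length are skipped); ``"com"`` averages molecular
    centers of mass unweighted.  The trajectory must be unwrapped.
    """
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
    n_lag = n if max_lag is None else min(n, int(max_lag / traj.frame_interval) + 1)
    msd = np.zeros(n)
    for lo in range(0, pos.shape[1], chunk):
        block = pos[:, lo : lo + chunk, :]
        msd += _msd_fft(block) @ weights[lo : lo + chunk]
    msd[0] = 0.0
    lags = np.arange(n_lag) * traj.frame_interval
    return MSDCurve(lag_times=lags, msd=msd[:n_lag], weighting=weighting)


def fit_einstein(
    curve: MSDCurve, window: tuple[float, float] = (100.0, 4000.0)
) -> EinsteinFit:
    """Self-diffusion coefficient from the Einstein relation MSD = 6 D t.

    Unweighted least squares of MSD on lag time over ``window`` (ps); the
    log-log slope over the same window is reported as a diagnostic of the
    diffusive regime (≈1 diffusive, ≈2 ballistic).
    """
    lo, hi = window
    mask = (curve.lag_times >= lo) & (curve.lag_times <= hi)
    if mask.sum() < 10:
        raise ValueError(
            f"window {window} ps contains only {int(mask.sum())} points "
            f"(lags reach {curve.lag_times[-1]:.0f} ps); need >= 10"
        )
    t = curve.lag_times[mask]
    y = curve.msd[mask]
    slope, _ = np.polyfit(t, y, 1)
    if np.any(y <= 0):
        raise ValueError("non-positive MSD values inside the fit window")
    ll_slope, _ = np.polyfit(np.log(t), np.log(y), 1)
    d_s = max(slope, 0.0) / 6.0 * CONSTANTS.msd_slope_to_SI
    return EinsteinFit(
        D_s=d_s,
        window=(float(lo), float(hi)),
        loglog_slope=float(ll_slope),
        diffusive=bool(abs(ll_slope - 1.0) <= 0.2),
    )


def arrhenius_fit(temps, rates) -> ArrheniusResult:
    """Activation energy from OLS of ln(rate) on 1/T: E_a = -slope · R.

    ``temps`` in K, ``rates`` positive in any consistent unit; E_a is
    returned in kJ/mol with a standard error propagated from the fit
    residuals (not from any externally quoted uncertainties).
    """
    T = np.asarray(temps, dtype=float)
    r = np.asarray(rates, dtype=float)
    if T.size != r.size or T.size < 2:
        raise ValueError("need >= 2 matched (temperature, rate) pairs")
    if np.unique(T).size < 2:
        raise ValueError("temperatures must include >= 2 distinct values")
    if np.any(r <= 0):
        raise ValueError("rates must be positive for an Arrhenius fit")
    x = 1.0 / T
    y = np.log(r)
    (slope, intercept), cov = np.polyfit(x, y, 1, cov=True) if T.size > 2 else (
        np.polyfit(x, y, 1),
        None,
    )
    fitted = slope * x + intercept
    resid = y - fitted
    e_a = -slope * CONSTANTS.R_gas / 1000.0  # kJ/mol
    if cov is not None:
        stderr = float(np.sqrt(cov[0, 0]) * CONSTANTS.R_gas / 1000.0)
    else:
        stderr = 0.0
    return ArrheniusResult(
        E_a=float(e_a),
        E_a_stderr=stderr,
        prefactor=float(np.exp(intercept)),
        residuals=resid,
    )
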