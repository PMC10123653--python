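"""Spectral decomposition and dynamical-model fits for QENS-like spectra.

Each S(Q, ω) is decomposed into [a_δ·δ + a₁·L(Γ₁) + a₂·L(Γ₂)] ⊛ R + b: an
optional elastic delta line, two Lorentzians of different widths, a flat
background, all convolved with the Gaussian instrument resolution R.  The
convolution is evaluated analytically — a Lorentzian ⊛ Gaussian is a Voigt
profile and δ ⊛ Gaussian is the resolution Gaussian itself — so no
numerical convolution grid enters.  Components are labelled by ascending
width: the narrow line tracks translational jump diffusion, the broad
Q-independent line localized (rotational) motion.

The Q dependence of the narrow width is fit with the Hall–Ross
jump-diffusion law

    HWHM(Q) = (ħ/τ) (1 - exp(-Q² d² / 2)),    D_s = d² / (2τ),

whose low-Q limit is the continuous-diffusion law ħ D_s Q².  This
parameterization binds (D_s, τ, d) together: the jump distance is always
√(2 D_s τ).  The broad width, constant in Q for isotropic rotational
diffusion, gives D_r through the leading-order (ℓ = 1) relation
HWHM = 2 ħ D_r.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from lmfit import Parameters, minimize
from scipy.special import voigt_profile
from scipy.stats import spearmanr

from .core import CONSTANTS
from .dsf import ResolutionModel
from .io import SpectrumTable

__all__ = [
    "QENSFitResult",
    "JumpDiffusionParams",
    "RotationParams",
    "fit_spectrum",
    "hall_ross_fit",
    "rotation_rate",
    "hall_ross_hwhm",
]


@dataclass
class QENSFitResult:
    """Per-Q spectral decomposition; widths in meV, labelled fwhm1 < fwhm2."""

    q: np.ndarray
    delta_amplitude: np.ndarray
    fwhm1: np.ndarray
    fwhm2: np.ndarray
    amplitude1: np.ndarray
    amplitude2: np.ndarray
    background: np.ndarray
    fwhm1_stderr: np.ndarray
    fwhm2_stderr: np.ndarray
    redchi: np.ndarray
    converged: np.ndarray


@dataclass
class JumpDiffusionParams:
    """Hall–Ross parameters; D_s = d²/(2τ) holds by construction."""

    D_s: float          # m²/s
    tau: float          # ps
    d: float            # Å
    tau_stderr: float | None = None
    d_stderr: float | None = None

    @property
    def D_s_1e10(self) -> float:
        """D_s in units of 1e-10 m²/s, the conventional tabulation scale."""
        return self.D_s / 1e-10


@dataclass
class RotationParams:
    D_r: float              # s^-1
    mean_fwhm: float        # meV
    per_q_scatter: float    # std of fwhm across Q, meV
    q_trend_flag: bool      # True when fwhm shows a strong monotone Q trend


def _model(params, energy: np.ndarray, sigma: float) -> np.ndarray:
    g1 = params["fwhm1"].value / 2.0
    g2 = params["fwhm2"].value / 2.0
    out = (
        params["a1"].value * voigt_profile(energy, sigma, g1)
        + params["a2"].value * voigt_profile(energy, sigma, g2)
        + params["bg"].value
    )
    a_d = params["a_delta"].value
    if a_d != 0.0:
        out = out + a_d * voigt_profile(energy, sigma, 0.0)
    return out


def fit_spectrum(
    spec: SpectrumTable,
    res: ResolutionModel | None = None,
    include_delta: bool = False,
) -> QENSFitResult:
    """Fit every Q cut with delta + two Lorentzians + flat background, all
    resolution-convolved.

    Multi-start nonlinear least squares (starting widths
    Γ₁ ∈ {0.02, 0.08} × Γ₂ ∈ {0.15, 0.4} meV, best χ² kept; width bounds
    [1e-4, 1] meV, amplitudes and background ≥ 0).  Two-Lorentzian fits are
    multimodal, hence the grid of starts.  Weighted by the provided
    uncertainties when present.  Non-converged Q values are flagged in
    ``converged``, never dropped.  The delta amplitude is only floated for
    experiment-like spectra (``include_delta=True``); simulated spectra have
    no container elastic line.
    """
    if res is None:
        res = ResolutionModel()
    energy = spec.energy
    if energy.size < 8:
        raise ValueError(f"need >= 8 energy points, got {energy.size}")
    if not np.any(spec.intensity > 0):
        raise ValueError("all intensities are zero")
    sigma = res.sigma_meV
    nq = spec.q.size
    out = {k: np.zeros(nq) for k in (
        "delta", "f1", "f2", "a1", "a2", "bg", "sf1", "sf2", "chi")}
    converged = np.zeros(nq, dtype=bool)

    for j in range(nq):
        y = spec.intensity[j]
        w = None
        if spec.uncertainty is not None:
            w = 1.0 / np.clip(spec.uncertainty[j], 1e-12, None)
        area = max(np.trapezoid(y, energy), 1e-12)

        def residual(params):
            r = _model(params, energy, sigma) - y
            return r * w if w is not None else r

        best = None
        for g1_0 in (0.02, 0.08):
            for g2_0 in (0.15, 0.4):
                params = Parameters()
                params.add("fwhm1", value=g1_0, min=1e-4, max=1.0)
                params.add("fwhm2", value=g2_0, min=1e-4, max=1.0)
                params.add("a1", value=0.5 * area, min=0.0)
                params.add("a2", value=0.3 * area, min=0.0)
                params.add("bg", value=max(float(y.min()), 0.0), min=0.0)
                if include_delta:
                    params.add("a_delta", value=0.1 * area, min=0.0)
                else:
                    params.add("a_delta", value=0.0, vary=False)
                try:
                    result = minimize(residual, params, method="leastsq")
                except Exception:
                    continue
                if best is None or result.chisqr < best.chisqr:
                    best = result
        if best is None:
            continue
        p = best.params
        f1, f2 = p["fwhm1"].value, p["fwhm2"].value
        a1, a2 = p["a1"].value, p["a2"].value
        s1 = p["fwhm1"].stderr or np.nan
        s2 = p["fwhm2"].stderr or np.nan
        if f1 > f2:  # enforce narrow-first labelling
            f1, f2, a1, a2, s1, s2 = f2, f1, a2, a1, s2, s1
        out["delta"][j] = p["a_delta"].value
        out["f1"][j], out["f2"][j] = f1, f2
        out["a1"][j], out["a2"][j] = a1, a2
        out["bg"][j] = p["bg"].value
        out["sf1"][j], out["sf2"][j] = s1, s2
        out["chi"][j] = best.redchi
        converged[j] = bool(best.success)

    return QENSFitResult(
        q=spec.q.copy(),
        delta_amplitude=out["delta"],
        fwhm1=out["f1"],
        fwhm2=out["f2"],
        amplitude1=out["a1"],
        amplitude2=out["a2"],
        background=out["bg"],
        fwhm1_stderr=out["sf1"],
        fwhm2_stderr=out["sf2"],
        redchi=out["chi"],
        converged=converged,
    )


def hall_ross_hwhm(q: np.ndarray, tau: float, d: float) -> np.ndarray:
    """Hall–Ross half-width (meV): (ħ/τ)(1 - exp(-Q²d²/2))."""
    q = np.asarray(q, dtype=float)
    return CONSTANTS.hbar / tau * (1.0 - np.exp(-(q**2) * d**2 / 2.0))


def hall_ross_fit(q, fwhm1) -> JumpDiffusionParams:
    """Fit the narrow-component widths with the Hall–Ross jump-diffusion law.

    ``fwhm1`` in meV on the Q grid (Å⁻¹); requires >= 4 points with
    positive widths.  Returns residence time τ (ps), jump-length parameter
    d (Å) and D_s = d²/(2τ) in m²/s.
    """
    q = np.asarray(getattr(q, "values", q), dtype=float)
    widths = np.asarray(fwhm1, dtype=float)
    if q.size < 4:
        raise ValueError(f"need >= 4 Q points, got {q.size}")
    if np.any(widths <= 0):
        raise ValueError("all widths must be positive")
    hwhm = widths / 2.0

    # initial values: plateau gives tau, low-Q curvature gives d
    tau0 = CONSTANTS.hbar / max(hwhm.max(), 1e-6)
    d0 = np.sqrt(
        np.clip(2.0 * tau0 * hwhm[0] / (CONSTANTS.hbar * q[0] ** 2), 0.01, 25.0)
    )
    params = Parameters()
    params.add("tau", value=tau0, min=1e-3, max=1e4)
    params.add("d", value=float(d0), min=1e-2, max=20.0)

    def residual(p):
        return hall_ross_hwhm(q, p["tau"].value, p["d"].value) - hwhm

    result = minimize(residual, params, method="leastsq")
    if not result.success:
        raise RuntimeError(f"Hall-Ross fit did not converge: {result.message}")
    tau = result.params["tau"].value
    d = result.params["d"].value
    if tau <= 0 or d <= 0:
        raise RuntimeError(f"non-physical Hall-Ross estimates tau={tau}, d={d}")
    d_s = d * d / (2.0 * tau) * CONSTANTS.msd_slope_to_SI  # Å²/ps -> m²/s
    return JumpDiffusionParams(
        D_s=d_s,
        tau=float(tau),
        d=float(d),
        tau_stderr=result.params["tau"].stderr,
        d_stderr=result.params["d"].stderr,
    )


def rotation_rate(q, fwhm2) -> RotationParams:
    """Isotropic rotational diffusion coefficient from the broad component.

    The broad width is Q-independent for localized rotation; its mean over
    Q gives D_r = HWHM / (2ħ) = fwhm / (4ħ) (leading Sears term, ℓ = 1).
    A strong monotone Q trend (Spearman |ρ| > 0.8) sets ``q_trend_flag``,
    signalling that the Q-independence assumption is violated.
    """
    q = np.asarray(getattr(q, "values", q), dtype=float)
    widths = np.asarray(fwhm2, dtype=float)
    if q.size < 2:
        raise ValueError("need >= 2 Q points")
    if np.any(widths <= 0):
        raise ValueError("all widths must be positive")
    mean_fwhm = float(widths.mean())
    d_r_ps = mean_fwhm / (4.0 * CONSTANTS.hbar)   # ps^-1
    rho = spearmanr(q, widths).statistic if np.ptp(widths) > 0 else 0.0
    return RotationParams(
        D_r=d_r_ps * 1e12,
        mean_fwhm=mean_fwhm,
        per_q_scatter=float(widths.std(ddof=1)) if widths.size > 1 else 0.0,
        q_trend_flag=bool(abs(rho) > 0.8),
    )
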