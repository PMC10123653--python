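"""ISF computation, resolution broadening, and the cosine transform to S(Q,ω)."""

import numpy as np
import pytest

from qensmd import (
    CONSTANTS,
    ISFSet,
    QGrid,
    ResolutionModel,
    apply_resolution,
    compute_incoherent_isf,
    default_qgrid,
    isf_to_dsf,
)

from conftest import make_trajectory

HBAR = CONSTANTS.hbar


def _lag_grid(t_max=400.0):
    return np.arange(0.0, t_max + 1.0)


def test_static_trajectory_has_unit_isf():
    isf = compute_incoherent_isf(make_trajectory(np.ones((30, 4, 3))), QGrid((0.4, 1.0)))
    np.testing.assert_allclose(isf.f, 1.0, atol=1e-12)


def test_isf_normalized_at_zero_lag(brownian_traj):
    isf = compute_incoherent_isf(brownian_traj, QGrid((0.6,)), max_lag=10, origin_stride=10)
    assert isf.f[0, 0] == 1.0


def test_brownian_isf_matches_gaussian_closed_form(brownian_traj):
    """F(Q, t) = exp(-D Q² t) for free Brownian scatterers."""
    isf = compute_incoherent_isf(
        brownian_traj, QGrid((0.4, 1.0, 1.6)), max_lag=50, origin_stride=4
    )
    d_ps = 5e-10 / CONSTANTS.msd_slope_to_SI
    for j, q in enumerate(isf.q):
        analytic = np.exp(-d_ps * q**2 * isf.lag_times)
        rms = np.sqrt(np.mean((isf.f[j] - analytic) ** 2))
        assert rms < 0.03


def test_isf_is_nonincreasing_in_q(brownian_traj):
    isf = compute_incoherent_isf(brownian_traj, default_qgrid(), max_lag=30, origin_stride=10)
    diffs = np.diff(isf.f[:, 1:], axis=0)
    assert np.all(diffs <= 1e-9)


def test_shell_sampling_agrees_with_sinc_kernel(brownian_traj):
    sub = make_trajectory(brownian_traj.positions[:300, :200])
    kw = dict(qgrid=QGrid((0.8,)), max_lag=20, origin_stride=10)
    exact = compute_incoherent_isf(sub, **kw)
    shell = compute_incoherent_isf(sub, method="shell", n_directions=96, seed=4, **kw)
    np.testing.assert_allclose(shell.f, exact.f, atol=0.02)


def test_resolution_zero_width_limit():
    t = _lag_grid(100)
    isf = ISFSet(q=np.array([1.0]), lag_times=t, f=np.exp(-0.01 * t)[None, :])
    out = apply_resolution(isf, ResolutionModel(1e-6))
    np.testing.assert_allclose(out.f, isf.f, rtol=1e-9)


def test_elastic_line_is_resolution_gaussian():
    """F ≡ 1 transforms to the resolution Gaussian (fwhm 17.5 μeV) within 2%."""
    t = _lag_grid(400)
    isf = ISFSet(q=np.array([1.0]), lag_times=t, f=np.ones((1, t.size)))
    res = ResolutionModel(17.5)
    spec = isf_to_dsf(apply_resolution(isf, res), n_energy_points=853)
    sig = res.sigma_meV
    analytic = np.exp(-spec.energy**2 / (2 * sig**2)) / (sig * np.sqrt(2 * np.pi))
    assert np.max(np.abs(spec.intensity[0] - analytic)) / analytic.max() < 0.02
    # integral over the window ~ F(0) = 1
    assert spec.parseval_integral[0] == pytest.approx(1.0, abs=0.01)


def test_exponential_isf_transforms_to_lorentzian():
    """F = exp(-t/τ_c) with ħ/τ_c = 100 μeV gives a Lorentzian of HWHM 100 μeV."""
    gamma = 0.1  # meV HWHM
    t = _lag_grid(400)
    isf = ISFSet(q=np.array([1.0]), lag_times=t, f=np.exp(-gamma * t / HBAR)[None, :])
    spec = isf_to_dsf(isf, require_resolution=False, n_energy_points=429)
    analytic = gamma / np.pi / (spec.energy**2 + gamma**2)
    assert np.max(np.abs(spec.intensity[0] - analytic)) / analytic.max() < 0.02


def test_dsf_is_symmetric_in_energy(brownian_traj):
    isf = compute_incoherent_isf(brownian_traj, QGrid((0.8,)), max_lag=100, origin_stride=10)
    spec = isf_to_dsf(apply_resolution(isf, ResolutionModel()), n_energy_points=101)
    np.testing.assert_allclose(spec.intensity[:, ::-1], spec.intensity, rtol=1e-10)


def test_energy_window_beyond_nyquist_rejected():
    t = _lag_grid(100)
    isf = ISFSet(q=np.array([1.0]), lag_times=t, f=np.ones((1, t.size)))
    with pytest.raises(ValueError, match="Nyquist"):
        isf_to_dsf(isf, energy_window=3.0, require_resolution=False)


def test_dsf_requires_resolution_unless_waived():
    t = _lag_grid(50)
    isf = ISFSet(q=np.array([1.0]), lag_times=t, f=np.ones((1, t.size)))
    with pytest.raises(ValueError, match="resolution"):
        isf_to_dsf(isf)


def test_qgrid_validation():
    with pytest.raises(ValueError):
        QGrid((0.4, 0.4))
    with pytest.raises(ValueError):
        QGrid((-0.2, 0.4))
    assert default_qgrid().values.size == 7
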