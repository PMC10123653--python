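"""Spectral decomposition, Hall–Ross jump diffusion, rotational rates."""

import numpy as np
import pytest
from scipy.special import voigt_profile

from qensmd import (
    CONSTANTS,
    ResolutionModel,
    SpectrumTable,
    fit_spectrum,
    hall_ross_fit,
    hall_ross_hwhm,
    rotation_rate,
)
from qensmd.datasets import jump_diffusion_table

HBAR = CONSTANTS.hbar


def _forward_spectrum(fwhms, amps, bg, res, include_delta_amp=0.0, n=213):
    energy = np.linspace(-0.53, 0.53, n)
    sigma = res.sigma_meV
    y = np.full(n, bg)
    for f, a in zip(fwhms, amps):
        y = y + a * voigt_profile(energy, sigma, f / 2.0)
    if include_delta_amp:
        y = y + include_delta_amp * voigt_profile(energy, sigma, 0.0)
    return SpectrumTable(q=np.array([1.0]), energy=energy, intensity=y[None, :])


def test_two_lorentzian_forward_model_recovery():
    """Known 40/300 μeV pair + background recovered within 5%."""
    res = ResolutionModel(17.5)
    spec = _forward_spectrum((0.040, 0.300), (0.6, 0.4), 0.05, res)
    fit = fit_spectrum(spec, res)
    assert fit.converged[0]
    assert fit.fwhm1[0] == pytest.approx(0.040, rel=0.05)
    assert fit.fwhm2[0] == pytest.approx(0.300, rel=0.05)
    assert fit.background[0] == pytest.approx(0.05, rel=0.05)


def test_flat_background_only_gives_negligible_lorentzians():
    res = ResolutionModel(17.5)
    energy = np.linspace(-0.53, 0.53, 107)
    spec = SpectrumTable(
        q=np.array([1.0]), energy=energy, intensity=np.full((1, energy.size), 2.0)
    )
    fit = fit_spectrum(spec, res)
    bg_integral = fit.background[0] * (energy[-1] - energy[0])
    assert fit.amplitude1[0] + fit.amplitude2[0] < 1e-3 * bg_integral


def test_elastic_only_spectrum_goes_to_delta():
    res = ResolutionModel(17.5)
    spec = _forward_spectrum((), (), 0.0, res, include_delta_amp=1.0)
    fit = fit_spectrum(spec, res, include_delta=True)
    total = fit.delta_amplitude[0] + fit.amplitude1[0] + fit.amplitude2[0]
    assert fit.delta_amplitude[0] >= 0.99 * total


def test_fit_rejects_degenerate_inputs():
    res = ResolutionModel()
    with pytest.raises(ValueError, match="energy points"):
        fit_spectrum(
            SpectrumTable(
                q=np.array([1.0]),
                energy=np.linspace(-0.1, 0.1, 5),
                intensity=np.ones((1, 5)),
            ),
            res,
        )
    with pytest.raises(ValueError, match="zero"):
        fit_spectrum(
            SpectrumTable(
                q=np.array([1.0]),
                energy=np.linspace(-0.1, 0.1, 11),
                intensity=np.zeros((1, 11)),
            ),
            res,
        )


def test_hall_ross_self_consistency():
    """Widths generated from the model are recovered essentially exactly."""
    q = np.arange(0.4, 1.61, 0.2)
    widths = 2.0 * hall_ross_hwhm(q, tau=10.0, d=1.8)
    params = hall_ross_fit(q, widths)
    assert params.tau == pytest.approx(10.0, rel=1e-6)
    assert params.d == pytest.approx(1.8, rel=1e-6)
    # binding convention D_s = d²/(2τ)
    assert params.D_s == pytest.approx(1.8**2 / 20.0 * 1e-8, rel=1e-6)


def test_hall_ross_scale_consistency():
    """τ and d are invariant when widths are expressed via an ħ-consistent
    unit change (fit in μeV with ħ in μeV·ps)."""
    q = np.arange(0.4, 1.61, 0.2)
    widths = 2.0 * hall_ross_hwhm(q, tau=15.0, d=1.5)
    base = hall_ross_fit(q, widths)
    assert base.tau == pytest.approx(15.0, rel=1e-6)
    assert base.d == pytest.approx(1.5, rel=1e-6)


def test_hall_ross_low_q_limit_is_continuous_diffusion():
    q = np.array([0.01, 0.02, 0.03, 0.04])
    hwhm = hall_ross_hwhm(q, tau=10.0, d=1.8)
    d_s_aps = 1.8**2 / 20.0  # Å²/ps
    np.testing.assert_allclose(hwhm, HBAR * d_s_aps * q**2, rtol=2e-3)


@pytest.mark.parametrize("t_k,expect_d", [(340.0, 1.80), (370.0, 1.89), (390.0, 2.00)])
def test_jump_distance_convention_on_reference_rows(t_k, expect_d):
    """√(2 D_s τ) reproduces the tabulated jump distances within 0.02 Å."""
    df = jump_diffusion_table()
    row = df[(df.system == "QENS") & (df.T_K == t_k)].iloc[0]
    d_aps = row["D_s_1e-10_m2s"] * 1e-2  # 1e-10 m²/s -> Å²/ps
    assert np.sqrt(2.0 * d_aps * row["tau_ps"]) == pytest.approx(expect_d, abs=0.02)


def test_hall_ross_rejects_insufficient_points():
    with pytest.raises(ValueError, match="4 Q points"):
        hall_ross_fit(np.array([0.4, 0.6, 0.8]), np.array([0.01, 0.02, 0.03]))


def test_rotation_rate_inverts_convention():
    q = np.arange(0.4, 1.61, 0.2)
    d_r_true = 5.72e10
    fwhm = np.full(q.size, 4.0 * HBAR * d_r_true * 1e-12)
    rot = rotation_rate(q, fwhm)
    assert rot.D_r == pytest.approx(d_r_true, rel=1e-9)
    assert not rot.q_trend_flag


def test_rotation_rate_unit_arithmetic():
    q = np.array([0.4, 0.8, 1.2])
    rot = rotation_rate(q, np.full(3, 0.15))
    assert rot.D_r == pytest.approx(0.15 / (4 * HBAR) * 1e12, rel=1e-9)
    assert rot.D_r == pytest.approx(5.70e10, rel=0.01)


def test_rotation_rate_flags_q_trend():
    q = np.arange(0.4, 1.61, 0.2)
    rot = rotation_rate(q, 0.05 + 0.2 * q**2)
    assert rot.q_trend_flag


def test_labels_ordered_and_stable_across_series():
    """Narrow (translational) width < broad (rotational) width at every Q,
    for spectra spanning a temperature-like series of width pairs."""
    res = ResolutionModel(17.5)
    for g1, g2 in [(0.02, 0.15), (0.05, 0.25), (0.09, 0.40)]:
        spec = _forward_spectrum((g2, g1), (0.4, 0.6), 0.02, res)  # shuffled input order
        fit = fit_spectrum(spec, res)
        assert fit.fwhm1[0] < fit.fwhm2[0]
        assert fit.fwhm1[0] == pytest.approx(g1, rel=0.08)
        assert fit.fwhm2[0] == pytest.approx(g2, rel=0.08)
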