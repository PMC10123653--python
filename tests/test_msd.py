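"""MSD computation, Einstein fits, Arrhenius activation energies."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from qensmd import arrhenius_fit, compute_msd, fit_einstein
from qensmd.datasets import (
    TEMPERATURES_K,
    jump_diffusion_table,
    msd_diffusion_table,
    reported_activation_energies,
    rotation_table,
)

from conftest import make_trajectory


def test_static_trajectory_has_zero_msd():
    curve = compute_msd(make_trajectory(np.ones((20, 3, 3))))
    np.testing.assert_allclose(curve.msd, 0.0, atol=1e-12)


def test_ballistic_drift_msd_is_quadratic():
    # 1D drift at 1 Å/ps: MSD(Δ) = Δ² exactly, independent of origin
    t = np.arange(50.0)
    pos = np.zeros((50, 2, 3))
    pos[:, :, 0] = t[:, None]
    curve = compute_msd(make_trajectory(pos))
    np.testing.assert_allclose(curve.msd, t**2, atol=1e-8)
    fit = fit_einstein(curve, window=(5, 45))
    assert fit.loglog_slope == pytest.approx(2.0, abs=0.01)
    assert not fit.diffusive


def test_brownian_msd_recovers_diffusion(brownian_traj):
    curve = compute_msd(brownian_traj)
    fit = fit_einstein(curve, window=(100, 1500))
    assert fit.D_s == pytest.approx(5e-10, rel=0.05)


def test_einstein_unit_conversion():
    lags = np.arange(0.0, 5000.0)
    curve_msd = 0.6 * lags
    from qensmd.msd import MSDCurve

    fit = fit_einstein(MSDCurve(lags, curve_msd, "b_inc"))
    assert fit.D_s == pytest.approx(1.0e-9, rel=1e-9)


def test_einstein_rejects_window_outside_data():
    from qensmd.msd import MSDCurve

    curve = MSDCurve(np.arange(50.0), np.arange(50.0), "b_inc")
    with pytest.raises(ValueError, match="window"):
        fit_einstein(curve, window=(100, 4000))


def test_msd_invariant_under_global_translation(brownian_traj):
    shifted = make_trajectory(brownian_traj.positions[:200] + 123.4)
    base = make_trajectory(brownian_traj.positions[:200])
    np.testing.assert_allclose(
        compute_msd(shifted).msd, compute_msd(base).msd, rtol=1e-8, atol=1e-8
    )


def test_arrhenius_translation_and_rotation_worked_examples():
    """Reference QENS rates reproduce the tabulated activation energies."""
    jump = jump_diffusion_table()
    qens = jump[jump.system == "QENS"].sort_values("T_K")
    fit = arrhenius_fit(qens.T_K, qens["D_s_1e-10_m2s"])
    assert fit.E_a == pytest.approx(22.7, abs=0.1)

    rot = rotation_table()
    qens_r = rot[rot.system == "QENS"].sort_values("T_K")
    fit_r = arrhenius_fit(qens_r.T_K, qens_r["D_r_1e10_s"])
    assert fit_r.E_a == pytest.approx(10.1, abs=0.1)


@pytest.mark.parametrize(
    "key,series",
    [
        ("QENS jump diffusion", ("jump", "QENS")),
        ("OPLS2005-DSF jump diffusion", ("jump", "OPLS2005-DSF")),
        ("OPLS3-DSF jump diffusion", ("jump", "OPLS3-DSF")),
        ("QENS rotation", ("rot", "QENS")),
        ("OPLS2005-DSF rotation", ("rot", "OPLS2005-DSF")),
        ("OPLS3-DSF rotation", ("rot", "OPLS3-DSF")),
        ("OPLS2005-MSD diffusion", ("msd", "OPLS2005-MSD")),
        ("OPLS3-MSD diffusion", ("msd", "OPLS3-MSD")),
    ],
)
def test_arrhenius_regression_against_reference_tables(key, series):
    """Every tabulated rate triple reproduces its tabulated E_a within 0.3 kJ/mol."""
    kind, system = series
    if kind == "jump":
        df, col = jump_diffusion_table(), "D_s_1e-10_m2s"
    elif kind == "rot":
        df, col = rotation_table(), "D_r_1e10_s"
    else:
        df, col = msd_diffusion_table(), "D_s_1e-10_m2s"
    sub = df[df.system == system].sort_values("T_K")
    fit = arrhenius_fit(sub.T_K, sub[col])
    assert fit.E_a == pytest.approx(reported_activation_energies()[key], abs=0.3)


def test_arrhenius_equal_rates_gives_zero_activation():
    fit = arrhenius_fit([340.0, 370.0, 390.0], [2.5, 2.5, 2.5])
    assert fit.E_a == pytest.approx(0.0, abs=1e-12)


@settings(max_examples=20, deadline=None, derandomize=True)
@given(scale=st.floats(0.1, 100.0))
def test_arrhenius_rate_scaling_moves_prefactor_not_ea(scale):
    temps = list(TEMPERATURES_K)
    rates = np.array([10.11, 18.40, 28.58])
    base = arrhenius_fit(temps, rates)
    scaled = arrhenius_fit(temps, rates * scale)
    assert scaled.E_a == pytest.approx(base.E_a, rel=1e-9)
    assert scaled.prefactor == pytest.approx(base.prefactor * scale, rel=1e-9)


def test_arrhenius_rejects_bad_inputs():
    with pytest.raises(ValueError, match="distinct"):
        arrhenius_fit([300.0, 300.0], [1.0, 2.0])
    with pytest.raises(ValueError, match="positive"):
        arrhenius_fit([300.0, 350.0], [1.0, -2.0])
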