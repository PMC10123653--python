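"""Reference dynamical coefficients for liquid p-cresol, 340–390 K.

Bundled worked-example inputs: self-diffusion coefficients, jump-diffusion
parameters, rotational rates and hydrogen-bond counts for bulk liquid
p-cresol as obtained from a QENS experiment (IRIS-type backscattering
spectrometer) and from molecular-dynamics simulations with two classical
force-field models (OPLS2005 and OPLS3), analyzed both over the instrument
time scale (via the simulated dynamic structure factor, "DSF") and over
4 ns (via mean squared displacements, "MSD").

These tables are *inputs* to the reporting layer — Arrhenius fits, the
jump-length convention check d = √(2 D_s τ), and the cross-series ratio
factors are all recomputed from them at run time.
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "TEMPERATURES_K",
    "jump_diffusion_table",
    "rotation_table",
    "msd_diffusion_table",
    "hbond_table",
    "reported_activation_energies",
]

TEMPERATURES_K = (340.0, 370.0, 390.0)

#: (system) -> D_s in 1e-10 m²/s, residence time tau in ps, jump distance d in Å
_JUMP = {
    "QENS": {
        "D_s": (10.11, 18.40, 28.58),
        "tau": (15.96, 9.68, 6.98),
        "d": (1.80, 1.89, 2.00),
    },
    "OPLS2005-DSF": {
        "D_s": (3.78, 11.35, 17.01),
        "tau": (18.43, 9.27, 8.07),
        "d": (1.18, 1.45, 1.66),
    },
    "OPLS3-DSF": {
        "D_s": (1.85, 6.27, 9.44),
        "tau": (50.17, 17.32, 9.08),
        "d": (1.36, 1.47, 1.31),
    },
}

#: (system) -> D_r in 1e10 s^-1
_ROTATION = {
    "QENS": (5.72, 7.10, 9.16),
    "OPLS2005-DSF": (4.62, 7.00, 7.30),
    "OPLS3-DSF": (3.00, 4.74, 6.57),
}

#: (force field) -> D_s in 1e-10 m²/s from 4 ns MSD analysis
_MSD = {
    "OPLS2005-MSD": (2.30, 6.13, 9.24),
    "OPLS3-MSD": (0.92, 3.36, 6.35),
}

#: (force field) -> mean hydrogen bonds per molecule
_HBOND = {
    "OPLS2005": (0.76, 0.63, 0.57),
    "OPLS3": (0.89, 0.74, 0.67),
}

#: reported activation energies, kJ/mol, for regression comparison
_EA = {
    "QENS jump diffusion": 22.69,
    "OPLS2005-DSF jump diffusion": 33.73,
    "OPLS3-DSF jump diffusion": 36.66,
    "QENS rotation": 10.07,
    "OPLS2005-DSF rotation": 10.57,
    "OPLS3-DSF rotation": 17.14,
    "OPLS2005-MSD diffusion": 31.06,
    "OPLS3-MSD diffusion": 42.88,
}


def jump_diffusion_table() -> pd.DataFrame:
    """Jump-diffusion parameters per system and temperature.

    Columns: system, T_K, D_s_1e-10_m2s (self-diffusion coefficient),
    tau_ps (residence time), d_A (jump distance).
    """
    rows = []
    for system, vals in _JUMP.items():
        for i, t in enumerate(TEMPERATURES_K):
            rows.append(
                {
                    "system": system,
                    "T_K": t,
                    "D_s_1e-10_m2s": vals["D_s"][i],
                    "tau_ps": vals["tau"][i],
                    "d_A": vals["d"][i],
                }
            )
    return pd.DataFrame(rows)


def rotation_table() -> pd.DataFrame:
    """Rotational diffusion coefficients (1e10 s⁻¹) per system and temperature."""
    rows = [
        {"system": s, "T_K": t, "D_r_1e10_s": v[i]}
        for s, v in _ROTATION.items()
        for i, t in enumerate(TEMPERATURES_K)
    ]
    return pd.DataFrame(rows)


def msd_diffusion_table() -> pd.DataFrame:
    """MSD-derived self-diffusion coefficients (1e-10 m²/s) per force field."""
    rows = [
        {"system": s, "T_K": t, "D_s_1e-10_m2s": v[i]}
        for s, v in _MSD.items()
        for i, t in enumerate(TEMPERATURES_K)
    ]
    return pd.DataFrame(rows)


def hbond_table() -> pd.DataFrame:
    """Mean hydrogen bonds per molecule per force field and temperature."""
    rows = [
        {"system": s, "T_K": t, "hbonds_per_molecule": v[i]}
        for s, v in _HBOND.items()
        for i, t in enumerate(TEMPERATURES_K)
    ]
    return pd.DataFrame(rows)


def reported_activation_energies() -> dict[str, float]:
    """Reference activation energies (kJ/mol) the Arrhenius fits are checked against."""
    return dict(_EA)
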