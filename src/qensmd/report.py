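"""Pipeline orchestration and cross-series comparison statistics.

``run_pipeline`` drives the whole chain from a validated config: generate
(or read) trajectories at each temperature, compute MSD/Einstein
coefficients, the incoherent ISF, resolution-broadened spectra, the
two-Lorentzian decomposition, Hall–Ross and rotation fits, Arrhenius
activation energies, and the comparison factors.  Every run is a pure
function of (config, seed): artifacts carry the config hash and seed.

Comparison conventions: "average factor" between two series is the
arithmetic mean of per-temperature ratios (not the ratio of means — the
two differ, and the former is the convention the tabulated liquid-state
factors follow); a "temperature factor" is the value at the highest
temperature over the value at the lowest.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__ as _version
from .core import Trajectory
from .dsf import QGrid, ResolutionModel, apply_resolution, compute_incoherent_isf, isf_to_dsf
from .fitting import JumpDiffusionParams, RotationParams, fit_spectrum, hall_ross_fit, rotation_rate
from .msd import arrhenius_fit, compute_msd, fit_einstein
from .synthetic import JumpRotSpec, generate_jump_rotation_trajectory, p_cresol_template

__all__ = [
    "SeriesTable",
    "PipelineConfig",
    "TemperaturePoint",
    "mean_ratio",
    "temperature_factor",
    "run_pipeline",
]


@dataclass(frozen=True)
class SeriesTable:
    """A labelled rate series on a sorted temperature grid."""

    label: str
    temperatures: tuple[float, ...]
    values: tuple[float, ...]

    def __post_init__(self) -> None:
        temps = tuple(float(t) for t in self.temperatures)
        vals = tuple(float(v) for v in self.values)
        object.__setattr__(self, "temperatures", temps)
        object.__setattr__(self, "values", vals)
        if len(temps) != len(vals):
            raise ValueError("temperatures and values must have equal length")
        if any(b <= a for a, b in zip(temps, temps[1:])):
            raise ValueError("temperatures must be sorted strictly ascending")


def mean_ratio(numerator: SeriesTable, denominator: SeriesTable) -> float:
    """Arithmetic mean over temperatures of the elementwise value ratio,
    rounded to 1 decimal (the precision such factors are quoted at)."""
    if numerator.temperatures != denominator.temperatures:
        raise ValueError(
            f"temperature grids differ: {numerator.temperatures} vs "
            f"{denominator.temperatures}"
        )
    den = np.asarray(denominator.values)
    if np.any(den == 0):
        raise ZeroDivisionError(f"zero value in denominator series {denominator.label!r}")
    ratios = np.asarray(numerator.values) / den
    return round(float(ratios.mean()), 1)


def temperature_factor(series: SeriesTable, decreasing: bool = False) -> float:
    """Value at the highest temperature over the value at the lowest,
    rounded to 1 decimal.  With ``decreasing=True`` the inverse is reported
    (the conventional way a decline with temperature is quoted, e.g. a
    hydrogen-bond count 'decreasing by a factor of 1.3')."""
    if len(series.values) < 2:
        raise ValueError("need >= 2 temperatures")
    lo, hi = series.values[0], series.values[-1]
    if decreasing:
        lo, hi = hi, lo
    if lo == 0:
        raise ZeroDivisionError(f"zero reference value in series {series.label!r}")
    return round(hi / lo, 1)


# ---------------------------------------------------------------------------
# pipeline


@dataclass(frozen=True)
class TemperaturePoint:
    """One synthetic 'temperature': a label plus the generator ground truth."""

    temperature_K: float
    tau: float            # ps
    sigma_jump: float     # Å
    D_rot: float          # s^-1


@dataclass(frozen=True)
class PipelineConfig:
    """Validated end-to-end pipeline configuration (synthetic route)."""

    points: tuple[TemperaturePoint, ...]
    n_molecules: int = 384
    cell_edge: float = 40.0
    n_frames: int = 5000
    frame_interval: float = 1.0
    vib_amp: float = 0.2
    q_moduli: tuple[float, ...] = (0.4, 0.6, 0.8, 1.0, 1.2, 1.4, 1.6)
    resolution_fwhm_ueV: float = 17.5
    energy_window: float = 0.53
    n_energy_points: int = 213
    msd_window: tuple[float, float] = (100.0, 4000.0)
    isf_max_lag: float | None = None
    origin_stride: int = 1
    seed: int = 1

    def __post_init__(self) -> None:
        if not self.points:
            raise ValueError("config needs at least one temperature point")
        temps = [p.temperature_K for p in self.points]
        if sorted(temps) != temps or len(set(temps)) != len(temps):
            raise ValueError("temperature points must be sorted and distinct")
        QGrid(self.q_moduli)  # validates
        if self.seed < 0 or self.seed >= 2**31:
            raise ValueError("seed must be in [0, 2^31)")

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        raw = dict(raw)
        pts = tuple(TemperaturePoint(**p) for p in raw.pop("points"))
        for key in ("q_moduli", "msd_window"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(points=pts, **raw)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if not isinstance(raw, dict) or "points" not in raw:
            raise ValueError(f"{path}: config must be a mapping with a 'points' list")
        return cls.from_dict(raw)

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True).encode()
        ).hexdigest()[:16]


def _analyze_trajectory(
    traj: Trajectory, config: PipelineConfig
) -> tuple[float, JumpDiffusionParams, RotationParams, dict]:
    """MSD → Einstein and ISF → DSF → fits for one trajectory."""
    msd_curve = compute_msd(traj, weighting="b_inc")
    window = config.msd_window
    max_lag = msd_curve.lag_times[-1]
    if window[1] > max_lag:  # scale the window to short clips
        window = (max(max_lag * 0.05, msd_curve.lag_times[1]), max_lag * 0.8)
    einstein = fit_einstein(msd_curve, window=window)

    isf = compute_incoherent_isf(
        traj,
        QGrid(config.q_moduli),
        max_lag=config.isf_max_lag,
        origin_stride=config.origin_stride,
    )
    res = ResolutionModel(config.resolution_fwhm_ueV)
    spectrum = isf_to_dsf(
        apply_resolution(isf, res),
        energy_window=config.energy_window,
        n_energy_points=config.n_energy_points,
    )
    fit = fit_spectrum(spectrum, res, include_delta=False)
    jump = hall_ross_fit(fit.q, fit.fwhm1)
    rot = rotation_rate(fit.q, fit.fwhm2)
    diag = {
        "msd_D_s_1e10": einstein.D_s / 1e-10,
        "loglog_slope": einstein.loglog_slope,
        "fwhm1": fit.fwhm1.tolist(),
        "fwhm2": fit.fwhm2.tolist(),
        "converged": fit.converged.tolist(),
    }
    return einstein.D_s, jump, rot, diag


def run_pipeline(config: PipelineConfig, outdir: str | Path | None = None) -> dict:
    """Execute the full synthetic chain and return (and optionally write)
    the report bundle.

    The bundle holds per-temperature D_s(T), τ(T), d(T), D_r(T), the
    generator ground truth, Arrhenius activation energies over the series,
    and provenance (config digest, seed, package version).  Deterministic
    given the config (per-point generator seeds are derived from
    ``config.seed``).
    """
    template = p_cresol_template()
    rows = []
    diagnostics = {}
    for i, pt in enumerate(config.points):
        spec = JumpRotSpec(
            tau=pt.tau,
            sigma_jump=pt.sigma_jump,
            D_rot=pt.D_rot,
            n_molecules=config.n_molecules,
            cell_edge=config.cell_edge,
            n_frames=config.n_frames,
            frame_interval=config.frame_interval,
            vib_amp=config.vib_amp,
            seed=(config.seed + 7919 * i) % (2**31),
        )
        try:
            traj = generate_jump_rotation_trajectory(spec, template)
            d_msd, jump, rot, diag = _analyze_trajectory(traj, config)
        except Exception as exc:
            raise RuntimeError(
                f"pipeline stage failed at T={pt.temperature_K} K "
                f"(config {config.digest()}): {exc}"
            ) from exc
        rows.append(
            {
                "T_K": pt.temperature_K,
                "D_s_dsf_1e10": jump.D_s_1e10,
                "tau_ps": jump.tau,
                "d_A": jump.d,
                "D_r_1e10_s": rot.D_r / 1e10,
                "D_s_msd_1e10": d_msd / 1e-10,
                "true_tau_ps": pt.tau,
                "true_d_A": pt.sigma_jump,
                "true_D_r_1e10_s": pt.D_rot / 1e10,
            }
        )
        diagnostics[f"T{pt.temperature_K:g}"] = diag
    table = pd.DataFrame(rows)

    report: dict = {
        "series": table,
        "diagnostics": diagnostics,
        "provenance": {
            "config_digest": config.digest(),
            "seed": config.seed,
            "version": _version,
        },
    }
    temps = table["T_K"].to_numpy()
    if len(temps) >= 2:
        report["E_a_translation_kJmol"] = arrhenius_fit(
            temps, table["D_s_dsf_1e10"].to_numpy()
        ).E_a
        report["E_a_rotation_kJmol"] = arrhenius_fit(
            temps, table["D_r_1e10_s"].to_numpy()
        ).E_a

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        table.to_csv(outdir / "series.tsv", sep="\t", index=False, float_format="%.6g")
        meta = {k: v for k, v in report.items() if k not in ("series", "diagnostics")}
        meta["diagnostics"] = diagnostics
        (outdir / "report.json").write_text(json.dumps(meta, indent=2))
    return report


def reference_factor_summary() -> dict[str, float]:
    """All cross-series comparison factors recomputed from the bundled
    reference tables (see :mod:`qensmd.datasets`)."""
    from . import datasets

    temps = datasets.TEMPERATURES_K
    jump = datasets.jump_diffusion_table()
    rot = datasets.rotation_table()
    msd = datasets.msd_diffusion_table()
    hb = datasets.hbond_table()

    def series(df, system, col):
        sub = df[df.system == system].sort_values("T_K")
        return SeriesTable(system, temps, tuple(sub[col]))

    qens_d = series(jump, "QENS", "D_s_1e-10_m2s")
    qens_r = series(rot, "QENS", "D_r_1e10_s")
    out = {
        "jump_ratio_qens_over_opls2005_dsf": mean_ratio(
            qens_d, series(jump, "OPLS2005-DSF", "D_s_1e-10_m2s")
        ),
        "jump_ratio_qens_over_opls3_dsf": mean_ratio(
            qens_d, series(jump, "OPLS3-DSF", "D_s_1e-10_m2s")
        ),
        "rotation_ratio_qens_over_opls2005": mean_ratio(
            qens_r, series(rot, "OPLS2005-DSF", "D_r_1e10_s")
        ),
        "rotation_ratio_qens_over_opls3": mean_ratio(
            qens_r, series(rot, "OPLS3-DSF", "D_r_1e10_s")
        ),
        "temp_factor_opls2005_msd": temperature_factor(
            series(msd, "OPLS2005-MSD", "D_s_1e-10_m2s")
        ),
        "temp_factor_opls3_msd": temperature_factor(
            series(msd, "OPLS3-MSD", "D_s_1e-10_m2s")
        ),
        "temp_factor_qens": temperature_factor(qens_d),
        "msd_ratio_qens_over_opls2005": mean_ratio(
            qens_d, series(msd, "OPLS2005-MSD", "D_s_1e-10_m2s")
        ),
        "msd_ratio_qens_over_opls3": mean_ratio(
            qens_d, series(msd, "OPLS3-MSD", "D_s_1e-10_m2s")
        ),
        "hbond_decrease_factor_opls2005": temperature_factor(
            series(hb, "OPLS2005", "hbonds_per_molecule"), decreasing=True
        ),
        "hbond_decrease_factor_opls3": temperature_factor(
            series(hb, "OPLS3", "hbonds_per_molecule"), decreasing=True
        ),
        "hbond_ratio_opls3_over_opls2005": mean_ratio(
            series(hb, "OPLS3", "hbonds_per_molecule"),
            series(hb, "OPLS2005", "hbonds_per_molecule"),
        ),
    }
    return out
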