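# Methods

`qensmd` implements a tandem analysis of molecular-liquid dynamics: the same
incoherent neutron-scattering observables are computed from a molecular
trajectory (real or synthetic) and fit with the same spectral and dynamical
models that are applied to quasielastic neutron scattering (QENS) spectra,
so that simulation and experiment can be compared on the instrument's own
time scale.  This note records the models, the conventions that bind the
derived quantities together, the numerical choices, and the known
limitations.

## Observables

**Mean squared displacement.**  MSD(Δ) is averaged over every time origin
(FFT correlator) and over atoms with weights ∝ b_inc², the squared
incoherent scattering length.  With the default table (H 25.274 fm, C and O
0), the MSD is in effect a hydrogen-motion observable, matching the neutron
sensitivity of organic liquids.  A center-of-mass mode averages molecular
centers unweighted.  Whether carbon/oxygen sites (with ≈0 incoherent
length) are nominally included is immaterial in the b_inc mode — their
weight is zero — so both weightings are exposed and the b_inc mode simply
skips zero-weight atoms.  The self-diffusion coefficient follows from the
Einstein relation MSD → 6·D_s·t by unweighted least squares on a lag
window, 100–4000 ps by default, where the log–log slope (reported as a
diagnostic) is ≈1; the log–log slope is never used in the fit itself.

**Incoherent intermediate scattering function.**  For an isotropic system
the powder average of exp(iQ·Δr) is exactly sinc(Q|Δr|), so

    F(Q, Δ) = Σ_α w_α ⟨ sinc(Q |r_α(t+Δ) − r_α(t)|) ⟩_t ,

with the same b_inc² weights, normalized so F(Q, 0) = 1.  The sinc kernel
removes the variance of explicit Q-direction sampling; a seeded
random-direction shell average is retained as a cross-check mode.  Time
origins can be strided to trade statistics for speed.  The default maximum
lag is min(n_frames/4·Δt, 200 ps), matching the ~100 ps window of a
17.5 μeV backscattering instrument; note that the resolution damping factor
at 200 ps is still ≈0.08, so analytic-limit checks that need the fully
decayed resolution Gaussian are run with ≥400 ps lag grids.

**Dynamic structure factor.**  The Gaussian instrument resolution
(fwhm 17.5 μeV by default, an IRIS-like graphite-002 setup) is applied in
the time domain as F·exp(−σ_E²t²/2ħ²) — the exact equivalent of convolving
S(Q,ω) with the resolution Gaussian.  S(Q,E) is then the discrete cosine
transform of the symmetrized F on a ±0.53 meV energy window, with a Hann
taper on the final 10% of lags to suppress truncation ringing (the taper
fraction is configurable; the untapered transform shows negative sidelobes
at the 1e-3 level).  Normalization: ∫S dE over the full line equals F(0);
the integral captured inside the finite window is recorded per Q.  No
detailed-balance factor is applied: classical trajectories give real,
symmetric F, and over ±0.53 meV at 340–390 K the quantum asymmetry is below
~2%.  Energy windows beyond the Nyquist limit πħ/Δt are rejected.

## Spectral model and fits

Each S(Q,ω) cut is decomposed as

    [a_δ·δ(ω) + a₁·L(Γ₁) + a₂·L(Γ₂)] ⊛ R(ω) + b ,

with unit-area Lorentzians parameterized by their fwhm Γ and a flat
background b.  The convolution is evaluated analytically: L ⊛ Gaussian is a
Voigt profile (`scipy.special.voigt_profile`) and δ ⊛ Gaussian is the
resolution Gaussian itself, so no numerical convolution grid (and none of
its discretization error) enters the model.  Two-Lorentzian fits are
multimodal; each cut is fit from a 2×2 grid of starting widths
(Γ₁ ∈ {0.02, 0.08} meV × Γ₂ ∈ {0.15, 0.4} meV) with bounds Γ ∈ [1e-4, 1]
meV and non-negative amplitudes/background, keeping the best χ².  Provided
uncertainties are used as weights when present; otherwise the fit is
unweighted.  Components are labelled by ascending width — narrow =
translation, broad = localized rotation.  The delta amplitude is only
floated for experiment-like spectra (it models elastic container
scattering); simulated spectra default to a_δ = 0.  Non-converged cuts are
flagged, never dropped.

**Jump diffusion (Hall–Ross).**  The narrow width vs Q is fit with

    HWHM(Q) = (ħ/τ)·[1 − exp(−Q²d²/2)],     D_s = d²/(2τ),

τ the mean residence time and d the jump-length parameter (the
per-component rms of the Gaussian jump-length distribution).  This
parameterization is
the one under which the three reference (D_s, τ, d) triples are mutually
consistent — d = √(2·D_s·τ) reproduces all tabulated jump distances within
0.02 Å — whereas the ⟨r²⟩/(6τ) convention does not; it is therefore the
binding convention of the package.  Its low-Q limit is the continuous
diffusion law ħD_sQ².

**Isotropic rotation.**  The broad width is Q-independent for rotational
diffusion; its mean over Q gives D_r through HWHM = 2ħD_r, the
leading-order (ℓ = 1) term of the Sears expansion.  A Spearman trend test
(|ρ| > 0.8 across Q) raises a flag when the Q-independence assumption is
violated.  This single-ℓ convention is what ties the sub-meV widths to
10¹⁰ s⁻¹-scale rates in the reference tables; see Limitations for its bias.

**Arrhenius.**  Activation energies are ordinary least squares of ln(rate)
on 1/T (two or more temperatures); E_a = −slope·R in kJ/mol, with the
standard error propagated from fit residuals.  Three-point fits reproduce
all eight tabulated reference activation energies to ±0.02 kJ/mol.

## Synthetic trajectories

The generator emulates the reference setup — 384 rigid p-cresol molecules
in a 40 Å periodic cube, positions every 1 ps for 5 ns — with independent
translation and rotation (the factorization the two-Lorentzian
decomposition assumes):

- **Translation** is a renewal process: residence times exponential with
  mean τ, jumps isotropic Gaussian with per-component rms σ.  This process
  has the exact laws MSD slope/6 = σ²/(2τ) and
  F(Q,t) = exp(−(t/τ)(1 − e^(−Q²σ²/2))) — i.e. Hall–Ross with d = σ — which
  is what makes full-chain recovery testable against closed forms rather
  than simulation.
- **In-cage vibration** is uncorrelated Gaussian jitter of rms 0.2 Å per
  component (a fixture choice — the reference analysis attributes its flat
  background to fast motions outside the instrument window but does not
  state an amplitude).  Frame-uncorrelated jitter contributes an elastic
  Debye–Waller factor plus a spectrally flat term, reproducing exactly the
  flat-background phenomenology.
- **Rotation** is rotational Brownian motion: successive small random
  rotations about space-fixed axes with rotation-vector variance 2·D_r·Δt
  per axis, substepped internally so each step stays below 0.05 rad²
  variance; this converges to isotropic rotational diffusion and remains
  valid at the fast reference-scale rates (D_r ≈ 6×10¹⁰ s⁻¹ means
  0.114 rad²/ps, i.e. 3 substeps).
- The 16-atom rigid p-cresol template (7 C, 8 H, 1 O; ring radius 1.397 Å,
  hydroxyl–methyl heavy-atom span 5.67 Å) uses idealized bond geometry;
  its hydrogens sit 2.5–3.5 Å from the center of mass.

Jump events are logged by the generator, so waiting-time statistics are
checked against the event log instead of re-inferring jumps from positions.
What the generator does **not** emulate: intermolecular forces and the
structure they create, translation–rotation coupling, internal (methyl,
hydroxyl) rotations, and thermostat artifacts.  Passing recovery tests
therefore demonstrate the correctness of the analysis chain for the modeled
dynamics, not force-field realism.

## Structure analysis

RDFs are intermolecular-only, minimum-image, normalized by the ideal-gas
pair density of the partner selection; n(r) is the cumulative neighbor
count of an A atom.  A hydrogen bond is geometric: intermolecular O···O
distance < 3.5 Å and at least one of the two O–H···O angles (measured at
the hydrogen, as deviation from linearity) within 180° ± 20°.  Each O–O
pair counts at most once — the per-molecule normalization by N/2 implies
undirected bonds — and the directed donor→acceptor count is reported
alongside for transparency.  The O–O cutoff can be re-derived from the
first minimum after the first peak of the O–O RDF via a helper rather than
hard-coded.  Planted-bond fixtures place bonded dimers and singleton
molecules on a jittered grid with all non-bonded O pairs ≥ ~4.5 Å apart, so
the planted count is exact by construction with margin in both distance and
angle.

## Problem sizes

Desk-scale defaults used by the test suite and the reproduction script:
recovery chains run 128 molecules × 2000 frames (tests) or 1500 frames
(script) at 1 ps, ISF origins strided by 4, spectra on 213 energy points
over ±0.53 meV at Q = 0.4–1.6 Å⁻¹ step 0.2.  Brownian oracles use 1000
particles × 2000 frames.  These sizes hold all statistical recovery errors
well below the tolerances being asserted.

## Known limitations

- **Two-Lorentzian protocol bias at Qr ≳ 2.**  For a rigid rotor with
  scattering hydrogens at radius r, the rotational spectrum is the Sears
  multiplet Σ_ℓ (2ℓ+1)j_ℓ²(Qr)·L(ℓ(ℓ+1)ħD_r); with p-cresol H radii
  (2.5–3.5 Å) and Q up to 1.6 Å⁻¹, the ℓ ≥ 2 lines dominate the
  quasielastic intensity at high Q.  A two-Lorentzian fit — the protocol
  this package reproduces — then inflates the narrow "translational" width
  by tens of percent at Q ≥ 1.0 and makes mean-fwhm₂/(4ħ) an
  amplitude-weighted effective rate ~2.5–3× the microscopic D_r.  A
  noise-free analytic forward model reproduces the same fitted widths as
  simulated trajectories to ~3%, confirming this is approximation bias of
  the protocol, not statistics or implementation.  Consequently τ from the
  full chain is biased low by ~20–40% and derived D_s high; the jump-length
  parameter d is robust (~5–10%), and temperature ordering of D_s is
  preserved.  Rates derived with this protocol are comparable *between*
  datasets analyzed the same way (the package's purpose) but are not
  unbiased estimates of the generator's microscopic parameters.
- The delta-free fit of a spectrum that is truly a single Lorentzian plus
  background (e.g. a center-of-mass spectrum with rotation absent) is
  continuum-degenerate in the second component; the fitted narrow width is
  then not meaningful.  Use the flagged amplitudes to detect this.
- Unwrapping requires per-frame displacements below half the cell edge;
  faster sampling is the only remedy for ambiguous unwraps.
- Non-orthorhombic cells, velocities/forces, coherent scattering,
  detailed-balance asymmetry, EISF-based geometry fitting, and
  multiple-scattering corrections are out of scope.
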