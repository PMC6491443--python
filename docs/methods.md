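# Methods

## Spectral arithmetic

Shifts between absorption maxima are computed on the photon-energy scale:
Δν̃ = 10⁷/λ_var − 10⁷/λ_ref (cm⁻¹, negative for red-shifts) and
E = K/λ with K = h·c·N_A = 28591.4 kcal·nm·mol⁻¹ (thermochemical calorie;
pinned in `constants.py` to six significant figures — all code and tests
refer to the pinned value rather than recomputing it). Integer reporting
of wavenumber shifts rounds halves away from zero, so a −1348.5 cm⁻¹
shift reports as −1349; the unrounded float is always retained alongside.
Additivity of combined mutations is assessed as deviation = combined −
Σ(components), computed with exact summation; components must share a
reference band.

The ν_C=C ↔ λ_max correlation is the empirical anti-correlation between
the retinal C=C stretching frequency and the absorption maximum, used here
as a fixed line with slope 70/270 cm⁻¹ per nm of red-shift and zero
intercept (both configurable through `CCStretchModel`).

## Chromophore geometry

The conjugated chain is represented by the heavy atoms C5…C15 plus the
Schiff-base N; the lysine CE extends the chain past N when present, which
is what makes the C15=N dihedral well defined. PDB input is parsed with
biotite; ATOM and HETATM records are both accepted, alternate locations
resolve to the highest-occupancy conformer, and atom matching is by
stripped-name equality. Hydrogens are ignored.

BLA is mean(formal single bonds) − mean(formal double bonds) with the
fixed convention: singles C6-C7, C8-C9, C10-C11, C12-C13, C14-C15;
doubles C5-C6, C7-C8, C9-C10, C11-C12, C13-C14 and the Schiff-base C15-N.
The bond sets are arguments of `bla()` for users with a different
convention. Dihedral distortion is the absolute deviation of each signed
dihedral from the nearest planar value (0°/180°), which maps twist angles
into [0°, 90°]. All metrics are invariant under rigid-body motion; signed
dihedrals change sign under mirror reflection while distortions do not.

The synthetic retinal builder produces a planar all-trans zig-zag (120°
bond angles, doubles at 1.35 Å, singles at 1.35 Å + BLA target) and then
applies requested twists by rotating the chain tail about each central
bond. In-memory geometries recover BLA and twist targets to 1e−6; PDB
text carries three decimals per coordinate, so round-trips through PDB are
accurate to roughly 1e−4 Å in bond lengths and a few hundredths of a
degree in dihedrals.

## Point-charge excitation surrogate

The electrostatic part of the S1−S0 gap is modelled as the difference of
Coulomb energies of two chromophore charge states against a fixed cavity
of residue-grouped point charges:

ΔE_elec = Σ_a Σ_s k_e (q_a^{S1} − q_a^{S0}) q_s / r_as, with
k_e = 332.0636 kcal·Å·mol⁻¹·e⁻², no cutoff, dielectric 1 (both
configurable). Sites closer than 0.5 Å to a chromophore atom raise a
singularity error. The total gap is ΔE_protein = ΔE_vacuum + ΔE_elec,
with ΔE_vacuum supplied by the caller — a published value, an external
electronic-structure result, or the affine surrogate below.

The default S0/S1 charge sets are explicitly illustrative: each state
carries +1e; S0 concentrates it on the Schiff-base end (N 0.45, C15 0.25,
C13 0.15, remainder spread evenly), S1 shifts it ring-ward (C5 0.25 and
0.15 on N, C13, C11, C9, C7). They are sign- and trend-correct — a
negative charge near N raises the gap (blue-shift), near C5 lowers it
(red-shift) — but are not ab initio populations; users can load their own
charges from TSV. Everything quantitative in the package rests on
bookkeeping identities, sign laws and superposition, not on these
defaults.

Charge-off analysis zeroes one residue's charges, recomputes the gap
(ΔE_off) and reports the contribution ΔE_protein − ΔE_off. Because the
Coulomb sum is linear in environment charges, per-residue contributions
superpose exactly to the total electrostatic term; this identity is
property-tested at 1e−9. Comparing two models classifies declared mutated
sites as *direct* and conserved residues whose contribution moved by more
than 0.01 kcal/mol (configurable) as *indirect*; the tolerance separates
numerical noise from genuine environment reorganization in fixtures.

`decompose_printed` is pure bookkeeping over published protein/vacuum gap
pairs: the electrostatic column and the deltas versus a reference are
recomputed exactly from the printed values. `flag_printed_deltas`
cross-checks published parenthetical deltas and reports any that differ
from the recomputed value by ≥0.05 kcal/mol; two vacuum parentheticals in
the bundled table fail this check at printed precision, and they are
flagged rather than silently "corrected" or matched.

The vacuum-gap surrogate is dE_vac = a + b·BLA + c·Σ|distortion| with
defaults a = 88.8593 kcal/mol, b = −396.658 kcal·mol⁻¹·Å⁻¹, c = 0,
obtained once by least squares over the four published (BLA, vacuum gap)
pairs; the calibration residuals are 0.25, 0.19, −0.83 and 0.40 kcal/mol.
No paired distortion data exist, so c defaults to zero and remains a user
knob. The surrogate stands in for gas-phase electronic-structure values
only to keep workflows runnable end to end; it carries no claim of
transferability beyond the calibration range (BLA ≈ 0.109–0.116 Å).

## Photocycle kinetics

The kinetic model is the irreversible first-order chain I1 → … → In →
ground with c1(0) = 1, evaluated by the Bateman closed form; chains with
rate constants equal to within a relative 1e−9 fall back to a
matrix-exponential evaluation, where the closed form is singular. The
closed form is verified against direct numerical integration of the rate
equations (LSODA, 1e−10 relative tolerance) as an independent oracle.

Simulated ΔA(t, λ) matrices are Σ_i c_i(t)·(ε_i − ε_ground)(λ) with
Gaussian bands in the wavenumber domain, plus Gaussian noise of
σ/√(n_averages), mimicking shot averaging; time grids are log-spaced by
convention. The KR2-flavoured default scheme has four intermediates with
lifetimes 30 µs, 300 µs, 1 ms and a final ground-state recovery of 4.8 ms
(the wild-type turnover; 8.2 ms for the double-mutant analogue), band
centers 545/535/470/605 nm versus a 525 nm ground state, and widths of
about 1100 cm⁻¹ — magnitudes typical of microbial-rhodopsin flash
photolysis.

Global fitting uses variable projection: the nonlinear search runs over
log-lifetimes only, with per-wavelength amplitudes (decay-associated
spectra) eliminated by linear least squares at every step
(Levenberg–Marquardt, uniform weights). Initial guesses default to a
log-spaced spread over the data's time range. Standard errors come from
the Gauss–Newton covariance of the log-lifetimes, mapped to lifetimes by
the delta method. Fits with nearly duplicated lifetimes (ratio < 1.05) or
components with relative amplitude norm < 1e−3 are flagged in
`diagnostics` — the typical signature of fitting one exponential too
many. The slowest fitted lifetime is reported as the turnover time; the
package does not attempt to distinguish whether such a printed value is an
O-decay constant or a full recovery time, it simply labels the slowest
component.

Rank-k SVD truncation is offered as the standard denoising step; the
Frobenius reconstruction error equals the norm of the discarded singular
values (Eckart–Young), which is asserted as an identity rather than a
tolerance.

## Assay estimators

Bleach difference spectra are analysed as after − before, so the destroyed
chromophore band appears as a negative lobe. The estimator fits
offset − A·exp(−(ν−ν₀)²/2σ²) in the wavenumber domain inside a 420–700 nm
window (excluding the retinal-oxime product band), then refits restricted
to ±1.5σ of the first-pass center so that tails of out-of-window bands
cannot tilt the fitted center; λ_max = 10⁷/ν₀, with its uncertainty
propagated from the fit covariance. The estimate is exactly invariant to
wavelength-independent baseline offsets. With the bundled generator
(0.5 AU band, σ = 1700 cm⁻¹, 0.002 AU noise on a 1 nm grid) the mean
recovery error is below 0.2 nm across the 515–569 nm range.

Initial transport rates are ordinary least-squares slopes of pH over
[t_on, t_on + w], default w = 10 s (≥10 samples at 1 Hz). For a
saturating response A(1 − e^{−t/τ}) the continuous-time OLS slope
underestimates the true initial rate A/τ by exactly w/(2τ), so windows at
or below τ/10 keep the bias within 5%; tests assert the limit at w = τ/12.
Relative activity is the slope ratio against a reference construct and is
exactly linear in trace amplitude.

## Synthetic data: what it does and does not emulate

The generators reproduce the *statistical structure* the estimators
assume: Gaussian band shapes in wavenumber, sequential-chain kinetics with
averaged Gaussian noise, saturating pH responses with an initial linear
regime, planar polyene geometry with controllable BLA and twists, and
net-neutral O-H-like dipoles (±q at 0.96 Å separation) oriented like the
study's key residues. They deliberately do not emulate instrument drift,
cosmic spikes, scattering baselines, photoselection/anisotropy,
instrument-response convolution, branched or reversible photocycles, or
real rotamer/hydrogen-bond network reorganization. Passing tests
therefore demonstrate correctness of the estimators and bookkeeping under
the stated model assumptions, not robustness to every artifact of real
spectrometer output. Published study numbers enter generators only as
parameters (e.g. 545 nm for the S254A band, 4.8 ms for the wild-type
turnover, BLA 0.1160 Å for the wild-type chain); assertions are always
recovery or bookkeeping statements. All stochastic generators are
deterministic under a fixed seed (package default 20190430).

## Numerical choices and degenerate inputs

- Wavenumber/energy constants are pinned (`constants.py`), never
  recomputed at import time.
- Half-integer wavenumber shifts round away from zero.
- Equal-rate kinetic chains switch to `expm`; the equality tolerance is
  relative 1e−9.
- Collinear atom triples make dihedrals undefined and raise a
  degenerate-geometry error; bonded distances outside 1.2–1.7 Å are
  rejected at construction.
- Coulomb singularities (site within 0.5 Å of the chromophore) raise
  rather than returning huge energies.
- The bleach fitter requires a negative lobe (identical before/after
  input raises an estimation error) and at least five points in the
  window; the slope estimator requires at least three points.

## Problem sizes

Default analysis sizes are chosen to match desk-scale practice: 50 × 200
transient-absorption grids with 20-seed recovery experiments, 1-nm
spectral grids over 330–750 nm, and 1 Hz pH traces of a few hundred
seconds. The full test suite runs in a few seconds on one CPU.

## Known limitations

- The point-charge surrogate has no polarization, no screening beyond a
  scalar dielectric, and fixed illustrative state charges; it reproduces
  sign structure and linear bookkeeping, not absolute gaps.
- The vacuum-gap surrogate is a two-parameter affine fit to four points;
  residuals up to 0.83 kcal/mol are inherent to that choice.
- Only strictly sequential, irreversible photocycles are implemented;
  the scheme type is extensible but branching/back-reaction fitting is
  out of scope.
- BLA bond classification is a declared convention; published BLA values
  computed under a different averaging would differ systematically.
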