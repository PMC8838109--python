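# Methods

This note records the models implemented in spindyn, the conventions and
defaults chosen where the literature leaves room, and what the synthetic
data generator does and does not emulate.

## Relaxation analysis

**Decay fitting.** Magnetization decays are fitted to a single
exponential I(t) = I0·exp(−t/T1) by nonlinear least squares
(scipy `curve_fit`), with starting values from a log-linear fit of the
positive intensities. One T1 per site is assumed, matching how
variable-temperature relaxation series of molecular crystals are
normally reduced; a stretched-exponential option exists on the
generator for robustness studies but is off by default. A two-point
decay is solved exactly (no standard error). Standard errors come from
the fit covariance; Monte-Carlo tests confirm they track the replicate
spread at the few-tens-of-percent level typical for 10–12-point decays.

**Arrhenius fits.** Activation energies are obtained by ordinary least
squares of ln R on 1/T — the slope of the linear parts of the
ln R vs 1/T plot — with E* = |slope|·R reported in kJ·mol⁻¹
(R = 8.314462618 J·mol⁻¹·K⁻¹). The *branch* is part of the result:
`slow` when rates rise on cooling (positive slope, motion slower than
the probe frequency), `fast` otherwise. Rather than silently choosing a
sign for the exponent in R = A·exp(±E*/RT), both the generator and the
fitter carry an explicit branch label. A window that straddles the
∧-shaped rate maximum (both flanks dropping by more than 0.2 in ln R)
triggers a warning advising split windows. Weighted fits are not the
default; ln-space OLS is what the slope-of-linear-parts procedure means.

**BPP model.** The heteronuclear dipolar rate is

    R = g · (3/20)(μ0/4π)² ħ² γH² γC² / r⁶ · [J(ωH−ωC) + 3J(ωC) + 6J(ωH+ωC)]

with the Lorentzian spectral density J(ω) = τ/(1+ω²τ²) and r = 1.09 Å
by default. The dimensionless `geometry_factor` g encodes the
motional-model convention for methyl three-site jumps. Published
treatments vary between roughly 2/3 and 8/9 (modulated fraction
1 − S_axis² = 8/9 at the 70.5° methyl geometry, with further reductions
for effective bond lengths and proton-multiplicity bookkeeping); the
default g = 3/4 lies in that range and reproduces published methyl
correlation times (a few ×10⁻¹¹ to ~10⁻¹⁰ s for T1 of 0.4–1.1 s at
125.7 MHz). It is a documented convention, fully overridable per call.
At fixed frequencies the lab-frame rate is unimodal in τ with its
maximum near ωC·τ ≈ 0.79 (verified against a symbolic-derivative
oracle).

**Rate inversion.** `invert_rate_to_tau` brackets the requested branch
of the unimodal BPP curve in log-τ space and solves by Brent's method
to 10⁻⁶ relative; a rate above the model maximum raises an error that
names the maximum. The rotating-frame expression appends a 1.5·J(2ω1)
term (Jones-type) to the lab-frame combination; it is a convention,
since the analysis itself only uses the operational matching rule
τ = 1/ν₁ (in Hz) at the R1ρ maximum — 16 µs at a 62.5 kHz spin lock.
The claim that a motion is "slow" is encoded only as a branch
classifier (τ above the lab-frame T1-minimum τ), never as a fitted
quantity.

## Dipolar couplings and order parameters

The rigid-limit one-bond coupling D_rig = (μ0/4π)γHγCħ/(2πr³) evaluates
to 23.33 kHz at r = 1.09 Å with CODATA constants. The Lee–Goldburg
scaling factor is the exact magic-angle cosine 1/√3 = 0.57735 by
default; the rounded-angle variant cos(54.7°) = 0.57786 is available
behind a flag so either convention is reproducible. Note 23.5 kHz × 1/√3
= 13.57 kHz; slightly lower quoted scaled rigid limits (~13.2 kHz)
correspond to a longer effective bond length (~22.9 kHz rigid limit).
Neither constant is silently reconciled; per-site r_CH overrides are the
supported mechanism.

**Pattern generation.** η = 0 powder patterns are generated from the
exact analytic density: each branch has ν(u) = (Δ/2)(3u²−1) with
u = cosθ uniform on [0,1], and per-bin masses are CDF differences, so
the edge singularities (horns at ±Δ/2) are integrated exactly instead of
sampled. Gaussian broadening (FWHM `lb`, default 0.1 kHz — the digital
resolution quoted for the indirect dimension of separated-local-field
experiments) is applied by convolution. "Splitting" throughout means the
horn-to-horn separation, which equals the (scaled) effective coupling.

**Splitting extraction.** Horn maxima are located as the two most
prominent local maxima above a robust noise floor (5× the point noise
estimated from second differences, and at least 10 % of the pattern
maximum), with parabolic sub-bin interpolation. Because convolution
pulls the maxima of an edge-singular lineshape inward by up to ~1.5
bins, the default method then refines Δ by least-squares fitting the
analytic broadened pattern (parameters Δ, σ, amplitude) seeded by the
horn estimate; this recovers generated couplings to well within one
frequency bin across D = 2–25 kHz, with or without the Lee–Goldburg
scale and at 2 % intensity noise. The horn-only estimator remains
available (`method="horns"`). The reported uncertainty is one bin — the
resolution-limited figure — divided by `scale_applied`, which is also
divided out of D_eff. An order parameter marginally above 1 (within
uncertainty/D_rig) is clipped to 1 with a flag.

## Motional models

S = 1 − (3/2)⟨θ²⟩ for small-amplitude axially symmetric wobble (θ in
radians internally, degrees at the interface; validity flagged beyond
30°, floored at 0), with the closed-form inverse
θ = √(2(1−S)/3). The N-site jump expression S = Σᵢⱼ pᵢpⱼP₂(cos θᵢⱼ)
takes explicit populations and a symmetric pairwise-angle matrix; it is
bounded in [−1/2, 1] and equals 1 only when all occupied orientations
coincide. For azimuthally uniform orientations on a cone of half-angle β
it converges to P₂(cos β)², consistent with the fast uniaxial-rotation
average S = P₂(cos β) (zero at the magic angle, −1/3 at the 70.5° methyl
geometry). Jump and uniaxial predictions of observable couplings use
|S|, since Pake splittings are sign-blind. The published 7°↔0.97 style
pairings are only approximately consistent with the formula itself
(7° gives 0.978), so banded comparisons are used in tests rather than
exact pairings. A motion averages one-bond dipolar couplings when
τ_c < 40 µs (strict inequality, configurable threshold).

## DSC thermodynamics

Peaks are integrated trapezoidally over temperature after subtracting a
linear baseline anchored at the window edges (a sigmoid baseline is
available behind a flag); heat-flow traces are first divided by the scan
rate, and the result is scaled to molar units with
M(simvastatin, C25H38O5) = 418.57 g·mol⁻¹ by default. A window edge
sitting more than 5 % of the peak height above the signal just outside
the window triggers a truncation warning with an estimated loss.
ΔS = 1000·ΔH/T_trans exactly; entropy integrals ∫cp/T dT use
trapezoidal quadrature with endpoint interpolation. cp steps are the
difference of linear flank extrapolations at T*, excluding a
configurable ±3 K band so a superimposed λ-peak does not bias the
flanks; the sign convention is above-minus-below (negative when cp
drops on heating). Temperatures read from files may be °C (converted by
+273.15; auto-detected below 150). Exo-up/exo-down is declared on the
trace. The free-rotor heat-capacity asymptote R/2 = 4.157 J·mol⁻¹·K⁻¹
is exposed as the documented interpretive bound for cp decreases across
order–disorder transitions.

The generator's λ-shape (cubic rise over four widths, sharp Gaussian
cut) is purely a fixture; only its integral, its cusp position and the
baseline step are contractually meaningful.

## Shielding–shift regression

Experimental shifts are regressed on computed isotropic shieldings
(δ = a·σ + b) by OLS, one model per element (¹H and ¹³C statistics are
quoted separately in practice). The slope is free by default — the
literature phrase "linear regression model" does not fix it — with a
fixed-slope(−1) referencing mode behind a flag. "Standard deviation"
is interpreted as the residual standard deviation with n−2 degrees of
freedom, and adjusted R² = 1 − (1−R²)(n−1)/(n−2). MAGRES files are
parsed by a small line-oriented reader of the `ms` block
(σ_iso = trace/3); the format is plain text and needs no heavier
machinery. Reproducing the published per-structure statistics exactly
requires the deposited MAGRES + assigned-shift tables (supplementary
data); the package's tests therefore calibrate the statistic on
synthetic data of the same size and scatter.

## Crystal geometry

Structures are read via gemmi. CIFs are expanded over all symmetry
operators to P1, merging duplicates within 0.3 Å (special positions);
PDB files are taken as deposited (CRYST1 + atoms). Coordinates are kept
fractional; Cartesian conversion uses the standard lower-triangular
cell matrix, and cell volumes use the triclinic closed form. Contacts
are found over the 3×3×3 image neighbourhood and reported once per pair
with the realising image shift; a brute-force all-images oracle checks
this on small cells. Void fractions count grid points (default spacing
0.2 Å, required ≤ probe/2) whose periodic distance to every atom
exceeds vdW + probe, with Bondi radii (H 1.20, C 1.70, O 1.52 Å) as the
named, swappable default — published void percentages are sensitive to
the radii set, so comparisons against them should be read with that in
mind. Hydrogen positions are used as-is. The default O…O hydrogen-bond
report cutoff is 3.2 Å.

## Synthetic data: what it does and does not emulate

The generator provides mono-exponential decays with relative Gaussian
noise, exactly log-linear Arrhenius rate series on an explicit branch,
exact η = 0 powder patterns, symmetric two-site Bloch–McConnell
exchange lineshapes (with k_AB = 2k·p_B so that the equal-population
coalescence occurs at the classical k = πΔν/√2), λ-shaped DSC traces
and hard-sphere toy cells. Noise levels default to 2 % relative — a
fixture choice, since the raw noise of the real experiments is not
published. Every generator takes one seed, derives a fresh
`numpy.random.default_rng` from it, and records it in the output
metadata; fixed seed means bit-identical output.

Passing tests on these fixtures demonstrates that the estimators invert
their generating models correctly and with calibrated uncertainties.
They do not demonstrate robustness to what real spectrometers add:
cross-polarization dynamics, spinning sidebands, t1 noise, baseline
roll, temperature gradients in the rotor (several K at fast spinning),
or multi-exponential relaxation from spin diffusion. No pulse-sequence
or spin-dynamics simulation is attempted.

## Pipeline and problem sizes

The pipeline joins per-site evidence (S, E*, branch, τ_c) and labels
regimes with config thresholds: fast if S ≤ 0.5 with fast-branch
activation, rigid if S ≥ 0.95 with a flat (≤ 2 kJ·mol⁻¹ or absent) E*,
intermediate otherwise. The thresholds sit in the gap between the
observed fast band (~0.33–0.38) and the restricted band (~0.91–1.00);
they are labels for reporting, not claims of phase identification, and
DSC transition temperatures are inputs to the interpretation, not
outputs of it. Reports are deterministic JSON (sorted keys, no
timestamps) plus a Markdown table; per-stage input hashes are logged
for provenance.

Test and acceptance computations use deliberately modest problem sizes —
8-point temperature series, 10–12-point decays, 200-replicate recovery
studies, 500-seed regression calibrations, ~10⁵-point void grids —
chosen so the full suite runs in seconds while keeping Monte-Carlo
standard errors well inside the asserted tolerances.

## Known limitations

* The methyl-jump geometry factor is a convention (see above); derived
  correlation times carry that convention and are compared in bands,
  not exactly.
* CSA and quadrupolar relaxation mechanisms are not modelled; order
  parameters come from dipolar couplings, not from model-free fits.
* η ≠ 0 dipolar tensors, 2D processing (phasing/shearing of
  separated-local-field spectra) and Hirshfeld-surface analyses are out
  of scope; slices arrive pre-extracted.
* Published void fractions and O…O distances for the deposited
  simvastatin polymorph structures can only be recomputed when the
  licence-gated CSD CIFs (EJEQAL, EJEQAL01, EJEQAL02) are supplied by
  the user.
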