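# spindyn

Variable-temperature solid-state NMR dynamics analysis for molecular
crystals, built around the polymorph problem of simvastatin: a drug
molecule whose ester tail rotates freely in the high-temperature crystal
form, locks into two-site conformational exchange in an intermediate
form, and freezes out in the low-temperature form, with two reversible
(enantiotropic) solid–solid transitions in between.

The package is for spectroscopists and materials scientists who have
variable-temperature relaxation series, separated-local-field dipolar
slices, DSC traces, GIPAW shielding calculations and crystal structures,
and want the standard reductions applied consistently:

* **relax** — mono-exponential T1/T1ρ fits; Arrhenius activation
  energies from ln R = ln A ± E*/RT (OLS of ln R on 1/T, E* = |slope|·R);
  the heteronuclear dipolar BPP model
  R = C·[J(ωH−ωC) + 3J(ωC) + 6J(ωH+ωC)], J(ω) = τ/(1+ω²τ²),
  inverted to correlation times on the fast or slow branch; the
  rotating-frame matching rule τ = 1/ν₁ at the R1ρ maximum.
* **dipolar** — rigid-limit one-bond C–H coupling
  D = (μ0/4π)·γHγCħ/(2πr³) (≈23.3 kHz at 1.09 Å), Lee–Goldburg scaling
  (1/√3), horn-splitting extraction from η = 0 Pake patterns, and order
  parameters S = D_eff/D_rig.
* **motion** — order parameter ↔ geometry: small-amplitude wobble
  S = 1 − (3/2)⟨θ²⟩, N-site jumps S = Σᵢⱼ pᵢpⱼP₂(cos θᵢⱼ), fast uniaxial
  rotation S = P₂(cos β), and the ~40 µs dipolar-averaging criterion.
* **thermo** — DSC peak integration to ΔH, transition entropies
  ΔS = ΔH/T, baseline heat-capacity steps, entropy integrals ∫cp/T dT,
  and the free-rotor cp asymptote R/2.
* **shiftreg** — MAGRES shielding files regressed against experimental
  shifts (per element), with residual sd and adjusted R².
* **xtalgeom** — unit-cell volumes, periodic O…O hydrogen-bond contact
  distances, probe-occupiable void fractions on a grid (Bondi radii).
* **synthgen** — synthetic versions of every input (decays, rate
  series, Pake patterns, exchange lineshapes, DSC traces, toy cells)
  with known ground truth, so the whole pipeline is testable without a
  spectrometer.
* **pipeline** — a YAML-configured run that joins the stages per site
  and labels motional regimes (fast / intermediate / rigid).

## Worked example

```python
import numpy as np
import spindyn as sd

# variable-temperature rates for the ester CH2 below the upper transition
truth = sd.GroundTruth(e_star=30.0, a=1.0, noise_sd=0.02, seed=5)
series = sd.gen_rate_series(truth, np.linspace(235, 270, 8), branch="slow")
print(sd.arrhenius_fit(series).summary())

# scaled dipolar slice of the same group -> order parameter -> wobble angle
pattern = sd.gen_pake(12.3, scale=sd.lg_scale(), lb=0.2, noise_sd=0.02, seed=5)
d_eff, unc = sd.extract_splitting(pattern)
res = sd.coupling_result(d_eff, d_rig=13.5, scale=pattern.scale_applied,
                         uncertainty=unc)
print(res.summary())
print(f"  theta_rms   : {sd.wobble_angle(res.s2):.1f} deg")

# DSC transition thermodynamics
trace = sd.gen_dsc(1.0, [(272.0, 1.13, 1.0)])
dh = sd.integrate_peak(trace, (262.0, 282.0))
print(f"dH = {dh:.3f} kJ/mol, dS = {sd.transition_entropy(dh, 272.0):.2f} J/(mol K)")
```

prints

```
Arrhenius fit (ln R vs 1/T, OLS)
  n points    : 8
  E*          : 29.833 +/- 0.269 kJ/mol
  ln A        : 0.074
  branch      : slow
  R-squared   : 0.99951
Dipolar coupling / order parameter
  D_eff : 12.310 +/- 0.173 kHz
  D_rig : 13.500 kHz
  scale : 0.57735
  S     : 0.912
  theta_rms   : 13.9 deg
dH = 1.130 kJ/mol, dS = 4.15 J/(mol K)
```

The rate series generated with a 30 kJ/mol barrier and 2 % noise is
recovered at 29.8 ± 0.3 kJ/mol on the slow branch (rates rising on
cooling); the Lee–Goldburg-scaled dipolar slice generated at 12.3 kHz
gives back D_eff = 12.31 kHz after de-scaling, i.e. S = 0.91 against a
13.5 kHz rigid limit, which the wobble model converts to a ~14°
root-mean-square fluctuation; and the synthetic λ-transition integrates
to ΔH = 1.13 kJ/mol, hence ΔS = ΔH/T = 4.15 J/(mol K) at 272 K.

There is also a thin CLI:

```sh
spindyn relax arrhenius rates.csv --window 240:270
spindyn dipolar fit slice.csv --scale lg --d-rig 13.5
spindyn thermo integrate dsc.csv --window 262:282
spindyn xtal voids structure.cif --probe 0.6 --grid 0.2
spindyn run config.yaml --out report.json
```

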