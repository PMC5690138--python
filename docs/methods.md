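# Methods

`m15tg43` characterizes the SPEC model M-15 HDR Iridium-192 brachytherapy
source: a desk-scale Monte Carlo photon-transport simulation produces
kerma tallies in water and air, and a TG-43U1 extraction stage converts them
into the clinical parameter set

D(r, θ) = S_K · Λ · [G_L(r,θ)/G_L(r₀,θ₀)] · g_L(r) · F(r,θ),

with r₀ = 1 cm, θ₀ = 90°, and θ = 0° at the distal (capsule-tip) end.
This note records the model, its assumptions, the defaults, and the known
limitations.

## Source model

The M-15 is modeled as nested coaxial cylinders from the manufacturer
dimensions: an iridium-metal core (0.06 cm diameter × 0.35 cm, 22.4 g/cm³)
centred inside a stainless-steel capsule (0.11 cm outer / 0.07 cm inner
diameter, 0.48 cm long, 7.8 g/cm³) with a steel drive cable (0.11 cm
diameter) attached at the proximal (θ = 180°) end.  The capsule interior
is not published beyond a schematic, so the simplest consistent layout is
used: flat ends, the core centred axially in the cavity with 0.02 cm
clearances, the residual cavity filled with the ambient medium, a 0.02 cm
tip wall, and solid steel between the cavity and the cable weld.  The cable
is modeled 6 cm long (configurable): beyond a few centimetres its dose
influence is confined to a narrow polar cone that is already fully shadowed.
The active length entering the geometry function is L = 0.35 cm.

## Physics data

* **Spectrum.** 24 principal gamma and K X-ray lines of Ir-192 decay
  (β⁻ → Pt-192 and EC → Os-192), curated from the standard compilations.
  Intensities are normalized so the total yield is exactly
  I_γ = 2.301 photons/decay and the per-line uncertainties rescaled so
  their intensity-weighted mean is exactly 0.5% — the two aggregates that
  are fixed points of the dataset.  L X-rays (≈9–10 keV) fall at or below
  the transport cutoff and are omitted.
* **Interaction coefficients.** Per-material CSV tables of μ/ρ and μen/ρ on
  a log grid covering 0.01–1.5 MeV for liquid water (0.998 g/cm³), dry air
  (STP, N/O/Ar/C = 0.7551/0.2318/0.0128/0.0003 by mass, 1.2929×10⁻³ g/cm³),
  iridium, and stainless steel (Fe/Cr/Ni = 70/19/11 by mass).  Attenuation
  is modeled as photoelectric absorption plus free-electron Klein–Nishina
  incoherent scattering; coherent (Rayleigh) scattering is excluded, in the
  tables and in the transport alike.  For water and air, the photoelectric
  part below 150 keV is recovered from the well-known μen/ρ values by
  subtracting the computed Klein–Nishina energy-transfer part; for iridium
  and steel, curated photoabsorption anchors are used (iridium K edge at
  76.11 keV kept as a sharp node pair).  Accuracy is ~0.5% on the water/air
  energy-absorption coefficients that control the kerma estimates and a few
  percent on the heavy-element photoelectric parts, which only modulate
  source self-absorption over ≤0.05 cm paths.  Interpolation is log-log
  linear, exact at nodes, with no extrapolation.

## Transport

Photon histories are generated uniformly inside the iridium core with
isotropic directions and line energies sampled from the spectrum.  Photons
are surface-tracked through core/cavity/capsule/cable with exponential free
paths from the total attenuation coefficient; interactions are photoelectric
absorption (history ends) or Compton scattering sampled exactly from the
free-electron Klein–Nishina distribution by rejection.  Histories end below
the 10 keV transport cutoff or on leaving the phantom.  Omitted physics —
coherent scattering, binding/Doppler corrections, K-fluorescence after
photoabsorption in the source, bremsstrahlung — contribute well under 1% at
Ir-192 energies.

**Kerma approximation.**  Collision kerma is scored instead of transporting
electrons: track length × E × μen/ρ per cell volume.  Secondary-electron
ranges in water are ≲2 mm at these energies, so collision kerma tracks
absorbed dose at every tallied radius (≥0.5 cm); this is the main systematic
concession of the desk-scale model and is covered by the ±2.5% band on the
absolute targets.

**Water mode.**  The source sits at the centre of a 50 cm-radius water
sphere ("pseudo-infinite": full scatter conditions at all tally radii).
Tally cells are full-azimuth spherical-shell rings centred on the polar grid
nodes — radial half-width min(0.25 mm + 2.5% r, 1 mm), angular half-width
0.5° — small enough that volume-averaging bias (≤0.2%) stays below the
statistical noise at 10⁷ histories.  Segment/cell intersections are solved
exactly: shell crossings analytically, polar-band crossings by monotone
bisection after splitting each flight at its radial and polar-cosine
extrema.  Cells are scored along every flight segment regardless of the
local medium, so cells that overlap the steel cable report water kerma at
that location.  The tally is kerma to water per source photon (MeV/g), the
same normalization as an energy-deposition tally per starting particle.

**Air mode.**  The ambient medium is vacuum; a 1 cm-radius air scoring
sphere sits 100 cm away on the transverse axis.  Because the source is
rotationally symmetric about its long axis, each escaping photon is scored
with its azimuth-averaged expected track length through the sphere (the
same symmetry argument as a ring detector), weighted by E × μen/ρ(air).
The closed form (R² − D*²)/(2 v √(ρ* d)) is exact to O((R/d)²) ≈ 10⁻⁴ and
reproduces the analog expectation V/(4πd²) for an isotropic point source;
at 10⁷ histories it reaches ~0.4% statistical precision where the analog
crossing estimator would be stuck at ~6%.  Photons at or below the X-ray
cutoff δ = 10 keV are excluded from scoring.  Attenuation and scatter in
the scoring air itself (~3×10⁻⁴) are neglected.  Air-kerma strength is the
converted kerma rate times d².

**Statistics and reproducibility.**  Runs are split into 50 batches with
per-batch seeds derived from the user seed; per-cell relative uncertainties
are batch standard errors.  A cell with no scored tracks reports its mean
as 0 with relative uncertainty 1.0 and is flagged.  Identical seed and
history count give bitwise-identical results.  Kernels are compiled with
numba; a pure-Python fallback keeps small runs usable without it.  No
variance reduction beyond the track-length estimators is applied.

## Extraction, uncertainties, fits

The extraction stage computes the normalized dose table
D_N = D·r²/D(r₀,θ₀), g_L and F via the line-source geometry function
(β evaluated as a difference of arctangents, exact at all angles; the
on-axis branch 1/(r²−L²/4) is used at both poles), the anisotropy factor
φ_an(r) by composite trapezoid quadrature of D·sinθ on the native
non-uniform angle grid (1° steps near the poles, 5° elsewhere), and the
anisotropy constant as the 1/r²-weighted mean of φ_an over r = 1…10 cm.
The unit conversion 1 MeV g⁻¹ Bq⁻¹ s⁻¹ = 3.7×10⁷ × 3600 × 1.602176634×10⁻⁸
≈ 2.134×10³ cGy mCi⁻¹ h⁻¹ is kept at full precision.

Uncertainties are propagated in quadrature: dose rates combine the cell's
MC error with the cross-section (default 1.5%, configurable) and photon
yield (0.5%) components; ratio quantities combine the two MC terms plus
twice the cross-section variance (their values near 1 therefore carry the
characteristic ±0.021); the anisotropy factor propagates per-angle
quadrature weights, reducing to the uniform-Δθ form on a uniform grid; for
F the reference MC term is the (r, θ₀) cell that actually enters the ratio.
The 1.5% cross-section default is back-solved from the ±0.021 envelope of
the published ratio tables and is the one free parameter of the budget.

g_L(r) is fitted to a 5th-order polynomial (in-range use; out-of-range
evaluation warns) and to a double exponential C1·e^(μ1 r) + C2·e^(μ2 r)
whose value at r = 0, C1+C2, is the recommended treatment-planning
extrapolation.  Rates may take either sign; fits use multi-start bounded
nonlinear least squares.  The amplitude bound |C| ≤ 1.2·max|g| matters:
unconstrained multi-exponential least squares on the 11-point table is
ill-posed and drifts to a near-cancelling pair (|C| ~ 65, nearly equal
rates) that fits marginally better in-range but extrapolates to a wrong
g(0).  With the bound, the fit of the published table gives g(0) = 0.995
with residual RMS 0.0016.

## Validation against the published tables

`dose_engine.validate` compares a computed dataset with the packaged
published tables cell by cell (z-scores from combined uncertainties) and on
the headline scalars.  One documented inconsistency drives its reporting
layout: with the published cable specification (solid steel, 7.8 g/cm³, on
the 180° axis) any faithful transport model predicts strong shadowing of
cells within ~3° of the proximal pole (deficits of 15–50% at 178–180°),
while the published tables show almost no cable attenuation anywhere
(e.g. their 170°/10° dose ratio implies ≲5% cable-side deficit where a
dense cable implies ~20%).  The published near-pole values and the
published cable specification cannot both hold; this package keeps the
faithful geometry.  `validate` therefore reports full-grid statistics and
"core" statistics (θ < 177°) and bases its pass flag on the core region.
At 10⁷ histories the core agreement is ≥99% of cells within 3σ and the
headline scalars land within 0.1–0.4%.

## Problem sizes and defaults

Defaults follow the study conditions: 100 cm-diameter water phantom,
100 cm air-kerma distance, δ = 10 keV, the published tally grid
(r = 0.5, 1…10 cm; θ = 0–10°/1°, 10–170°/5°, 170–180°/1°).  The packaged
simulations run 10⁷ histories in 50 batches — the desk-scale point where
the reference-cell MC error is ~0.4%, far from the ~0.01% of a
4×10⁹-history production run; agreement with the published absolute values
is therefore statistical within ±2.5%, and the near-pole cells (tiny ring
volumes) remain noisy by design.

## What the synthetic data do and do not show

The transport stage is a simplified stand-in for a general-purpose code:
it emulates F6-style kerma tallies and a *F4-style air-kerma tally with
per-cell batch uncertainties, which suffices to exercise the entire
extraction/uncertainty/fitting/validation stack and to reproduce the
headline dosimetry to well within its tolerance.  It does not demonstrate
electron-transport effects below 0.5 cm, spectral fidelity beyond the line
approximation, phantom-size effects, or the behaviour of a real afterloader
geometry; conclusions about real clinical sources should rest on the
published consensus data, which the package carries verbatim.
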