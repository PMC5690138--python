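# m15tg43

Monte Carlo dosimetric characterization of the SPEC model M-15 HDR
Iridium-192 brachytherapy source, with full TG-43U1 parameter extraction.

The package is aimed at medical physicists and Monte Carlo dosimetry
developers: it couples a desk-scale photon-transport simulator (kerma
approximation, Klein–Nishina scattering, exact track-length ring tallies)
to the complete AAPM/ESTRO TG-43U1 analysis stack, and ships the published
M-15 consensus tables as machine-readable references.

At its core is the TG-43U1 dose equation

    D(r, θ) = S_K · Λ · [G_L(r,θ) / G_L(r₀,θ₀)] · g_L(r) · F(r,θ)

with the line-source geometry function G_L(r,θ) = β/(L r sinθ), the radial
dose function g_L(r), the anisotropy function F(r,θ), the air-kerma
strength S_K (kerma rate in free space × d²), and the dose-rate constant
Λ = D(1 cm, 90°)/S_K.  Everything upstream of these parameters — the
source geometry, the Ir-192 spectrum (I_γ = 2.301 photons/decay), the
water/air/iridium/steel interaction tables, the transport, the batch
statistics, and the quadrature uncertainty propagation — lives in the
package; see `docs/methods.md` for the model and its assumptions.

## Worked example

```python
import numpy as np
import m15tg43 as m

spectrum = m.load_spectrum()            # I_gamma = 2.301 photons/decay
geometry = m.build_m15()                # Table-1 dimensions, cable at 180 deg
grid = m.TallyGridSpec(np.array([1.0]), np.array([90.0]))

water = m.simulate_water(geometry, spectrum, grid,
                         n_histories=10**6, seed=1, n_batches=50)
air = m.simulate_air_kerma(geometry, spectrum, n_histories=10**6, seed=2)

d_ref = m.dose_rate(water.at(1.0, 90.0), spectrum.total_yield)
sk = m.air_kerma_strength(air, spectrum.total_yield)
print(f"D(r0,theta0) = {d_ref:.3f} cGy/(mCi h)")
print(f"S_K          = {sk:.3f} U/mCi")
print(f"Lambda       = {m.dose_rate_constant(d_ref, sk):.3f} cGy/(h U)")
```

prints (seeds as above, one minute on a laptop):

```
D(r0,theta0) = 4.078 cGy/(mCi h)   (published 4.038 +/- 0.064)
S_K          = 3.666 U/mCi           (published 3.632 +/- 0.086)
Lambda       = 1.112 cGy/(h U)  (published 1.112 +/- 0.029)
```

The reference dose rate in water and the air-kerma strength land within
their ~1% statistical error at 10⁶ histories; their ratio, the dose-rate
constant, reproduces the published 1.112 cGy h⁻¹ U⁻¹.  The published
tables themselves are available for downstream work:

```python
ref = m.load_reference_tables()
fit = m.fit_radial(ref.radial_dose["r_cm"], ref.radial_dose["g_L"],
                   "double_exponential")
print(f"g_L(0) = {fit.g_at_zero:.3f}")          # 0.995 (published 0.994)

dataset = m.build_reference_dataset()           # consensus TG-43 dataset
m.dose_at(dataset, 10.0, 2.0, 30.0)             # 2.587 cGy/h for a 10 U source
```

A command-line interface mirrors the library
(`m15tg43 run-all --histories 10000000 --seed 1 --out run/`, plus
`simulate-water`, `simulate-air`, `extract`, `fit`, `dose`, `validate`).

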