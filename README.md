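# escmech

Quantitative analyses for comparing the mechanics and actin architecture
of mouse embryonic stem cells grown in two culture media: naive **2i**
(dome-like colonies, disordered cortical actin) and primed **Serum/LIF**
(spreading colonies, aligned stress fibres). The package is aimed at
biophysicists doing optical-tweezers passive micro-rheology and
single-molecule localization microscopy (STORM) of the cytoskeleton, and
provides four analysis stages plus synthetic-data generators that carry
their ground truth, so every estimator can be validated end to end.

## What it computes

**Passive micro-rheology** from a trapped tracer's position time series
`x(t)` (quadrant photodiode, 22 kHz):

- one-sided power spectral density `P(f)` (Welch), and the scaling
  exponent `α` of `P(f) ∝ f^−(1+α)` fitted over 300–3000 Hz, where
  thermal fluctuations dominate. `α = 1` is Brownian (viscous),
  `0 < α < 1` sub-diffusive (elastic-like); equivalently `MSD(τ) ∝ τ^α`.
- complex shear moduli through the fluctuation–dissipation theorem,
  `χ″(f) = π f S(f) / (k_B T)` with `S` the two-sided density, a
  Kramers–Kronig principal-value transform for `χ′(f)` (trustworthy for
  `f < f_Nyquist/10`), and the generalized Stokes–Einstein relation
  `G*(f) = 1 / (6 π r χ(f))`, giving storage `G′` and loss `G″`. The
  optical trap's constant elastic contribution `G′_trap = k/(6 π r)` is
  subtracted.

**STORM post-processing**: reading/writing the comma-separated
localization dialect (`frame, x [nm], y [nm], …`), rendering,
lateral drift correction by cross-correlation of temporally binned
renderings, astigmatism z-calibration from bead stacks
(`log(σx/σy)` vs z, odd-cubic fit) and per-event z assignment.

**Actin orientation**: Gabor-bank ridge enhancement, per-pixel
orientation/coherence from the structure tensor, polar histograms, and
the nematic order parameter `S = ⟨cos 2θ⟩` relative to the cell's major
axis (1 = aligned, 0 = isotropic, −1 = perpendicular).

**Morphometry**: colony–substrate contact angle from side-view masks
(sub-pixel boundary + circle fit at the contact line), per-cell contact
area within the TIRF volume, and moment-ellipse aspect ratio.

**Group statistics**: D'Agostino–Pearson normality check and Student's
t-test, orchestrated into two reproducible condition-comparison studies.

## Worked example

`examples/02_scaling_exponent_study.py` runs the two-condition
micro-rheology study on synthetic granule trajectories (26 granules per
condition, true exponents drawn around 0.48 vs 0.40):

```
per-condition scaling exponents (26 granules each):
  2i         fitted alpha = 0.526 +- 0.111 (generator truth mean 0.524)
  Serum/LIF  fitted alpha = 0.374 +- 0.157 (generator truth mean 0.382)

normality p-values: 0.72, 0.20
t = 4.01, p = 0.0002 -> significant at 0.05
```

The fitted group means track the generator truth to ~0.01, both
distributions pass the normality check, and the t-test separates the
conditions — the naive-like group sits closer to viscous behaviour.
`examples/01_trapped_bead_moduli.py` runs the full moduli chain on a
trapped bead in water and prints a flat `G′ ≈ 10.5 Pa` plateau against
the analytic `k/(6πr) = 10.6 Pa` with `G″/(2πf)` returning the viscosity
of water within a few percent; the other examples demonstrate drift
correction (100 nm drift corrected to a 4 nm residual), astigmatic z
(200 nm recovered to ~1 nm), the order parameter (aligned S = 0.95 vs
isotropic S = −0.02) and contact angles (115° and 69° phantoms recovered
within a degree).

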