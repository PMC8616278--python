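# Methods

This note documents the models, conventions and numerical choices
behind each analysis stage, what the synthetic generators do and do not
emulate, and the known limitations.

## Micro-rheology

### Spectral conventions

All spectra are one-sided densities on a positive frequency grid with
`Σ P(f)·Δf = var(x)`; positions are nm, so `P` is nm²/Hz. The DC bin is
excluded. `compute_psd` defaults to Welch averaging (Hann window, 50 %
overlap) for variance reduction; an unwindowed single-segment mode
exists and satisfies Parseval's identity to machine precision, which the
tests use as an anchor.

### Scaling exponent

`fit_scaling_exponent` fits `log10 P` vs `log10 f` by ordinary least
squares over quarter-decade log bins inside the band (default
300–3000 Hz; below the trap corner frequency at the laser powers
emulated, above the regime where active cellular processes contribute).
Ordinates are arithmetic bin means: periodogram ordinates are
exponentially distributed, and averaging before the logarithm removes
the `−γ` bias of `E[log P̂]` without maximum-likelihood machinery. The
residual curvature of binning an exact power law costs ≤ 0.001 in α.
`α = −slope − 1`; the standard error comes from the regression. Regime
classification uses `|α − 1| ≤ 0.05` for "brownian" (no tolerance is
standard; 0.05 matches the fit's ensemble spread at the default sizes).

### Response function and moduli

The fluctuation–dissipation theorem links the equilibrium position
spectrum to the dissipative response: `χ″(ω) = ω S_x(ω) / (2 k_B T)`
with `S_x` the two-sided density, i.e. `χ″(f) = π f (P(f)/2) / (k_B T)`
for our one-sided `P`. The factor of two is fixed by the harmonic-trap
oracle: pushing the exact Ornstein–Uhlenbeck spectrum through the chain
must return `G′ = k/(6πr)` and `G″ = 2πfη`, which it does (tests).

`kramers_kronig_real` evaluates
`χ′(f) = (2/π) PV ∫₀^F f″χ″(f″)/(f″²−f²) df″` by singularity
subtraction: the constant `f χ″(f)` is removed from the integrand (its
principal-value integral over `[0, F]` has a closed form) and the
removable singularity at `f″ = f` is filled with a finite-difference
derivative; elsewhere the trapezoid rule runs on the native grid. Two
tail policies exist:

- `tail="power_law"` (default): `χ″` is extended beyond the grid by the
  power law fitted to its last half-decade. For analytically known
  responses this removes the `O(χ″(F))` truncation error and reproduces
  the Lorentzian Hilbert pair within 3 % below `F/10`.
- `tail="none"`: used by `moduli_from_trajectory` for spectra estimated
  from sampled signals. A sampled spectrum is aliased: power above
  Nyquist folds back below it, and for the `~f⁻²`-type spectra here the
  folded power plays quantitatively the role of the truncated tail,
  while a power law fitted to the alias-distorted high-frequency end
  would be badly wrong. This choice is validated by the full-chain
  water-calibration oracle.

Either way the reconstruction degrades approaching the grid edge — the
sampled signal carries no information beyond Nyquist — so moduli are
only reported for `f ≤ f_Nyquist/10` (`kk_valid_max`; 1100 Hz at
22 kHz), and the tests confirm the error growth above that cap.

The generalized Stokes–Einstein relation is implemented as the complex
inversion `G* = 1/(6πr·χ)`; its prefactor is the only dimensionally
consistent reading of the relation. `subtract_trap` removes the
measured constant `G′_trap` from the storage modulus exactly once
(double subtraction is a state error); the trap constant is an input,
measured on a calibration bead in water, not estimated here.

Single-bin moduli are noisy (the exponential periodogram statistics
propagate); `log_band_average` provides the quarter-decade band
averaging used for reported curves.

### MSD

`compute_msd` evaluates the time-averaged MSD on a log-spaced lag grid
and fits `MSD ∝ τ^α` over lags `τ ∈ [1/3000, 1/300] s`, the mirror of
the spectral band; PSD- and MSD-based exponents agree within 0.1 on
synthetic power-law trajectories.

### Parameters

- temperature: default 310.15 K (cells at 37 °C); calibration examples
  use 300 K explicitly.
- tracer radius: required input (granule radii are sample-specific);
  the study runner defaults to 250 nm, a typical lipid-granule radius.
- one lateral axis is analysed per trajectory record.

## Synthetic trajectories

`simulate_power_law_trajectory` synthesises Fourier coefficients with
`E|X_k|²` matching the target `P(f) = A / (f_c^(1+α) + f^(1+α))` —
a power law above a trap plateau that reduces exactly to the Lorentzian
at α = 1 — with independent Gaussian real/imaginary parts, so
periodogram ordinates are exponential, as for real spectral estimates.
Power-of-two lengths keep the synthesis grid exact; O(n log n), bit
reproducible by seed. Spectral synthesis produces a stationary Gaussian
surrogate with the right second-order statistics; it does not emulate
non-equilibrium activity, intermittency, or amplitude non-Gaussianity
of real cytoplasm.

`simulate_trapped_viscous_trajectory` uses the exact Ornstein–Uhlenbeck
discretization (`x_{n+1} = ρ x_n + σ_eq √(1−ρ²) ξ`, `ρ = e^{−Δt/τ}`),
so no step-size bias contaminates the moduli oracle; equipartition
(`var = k_B T/k`) holds by construction. `simulate_brownian_trajectory`
is a cumulative sum of Gaussian increments; note that the *sampled*
random walk's spectrum is `∝ 1/sin²(πf/f_s)`, slightly shallower than
`f⁻²` near Nyquist, which biases the fitted mean α to ≈ 0.97–0.98 —
within the 0.05 recovery tolerance, and a property of any finite
sampling rate, not of the estimator.

## Localization post-processing

Tables are nm, origin top-left, y down, 1-based frames — the dialect of
the upstream localization tool, whose headers (`"x [nm]"`, tolerant of
spacing) are parsed by suffix. Unknown columns ride along untouched.
Raw spot detection/PSF fitting is out of scope (done upstream).

Drift: events are split into equal frame-range bins (default 10; sparse
bins merge with a warning), each bin is rendered at 20 nm pixels, and
bin *i* is registered to bin 1 by the upsampled cross-correlation peak
(default ×10). The model interpolates linearly between bin centers,
anchored at zero in the first bin, and is subtracted per event. The
estimator's practical precision on blinking data is a few nm —
set by event counts and localization noise rather than by the
upsampling grid — and correction is idempotent at that level.

Astigmatism: the elongation metric is `log(σx/σy)` (antisymmetric in z,
zero at focus), fitted per bead-stack z-plane medians with an odd cubic
through the origin; the valid range is the largest interval of strict
monotonicity containing the focus, inside which the curve is inverted
numerically for z assignment. Events with elongation outside that range
are dropped and counted (`meta['dropped_out_of_range']`) so filters are
auditable. The synthetic defocus model
(`σ(z) = σ₀√(1+((z±c)/d)²)`, c = 300 nm, d = 400 nm) saturates and
folds back beyond |z| ≈ 500 nm, as real astigmatic PSFs do; elongation
alone cannot detect that aliasing, which is why the valid range matters.
Bernoulli blinking with Gaussian localization noise is emulated;
EMCCD noise physics, photobleaching and multi-emitter overlap are not.

## Orientation analysis

Gabor enhancement (even-symmetric bank over [0°, 180°), default 18
orientations, wavelength 8 px, σ = 3 px at 20 nm rendering pixels —
matching 100–200 nm bundle widths) precedes the structure tensor.
The tensor uses Gaussian-derivative gradients at σ = 1.5 px smoothed at
window σ = 2.5 px; angle `= ½ atan2(2Jxy, Jxx−Jyy) + 90°` (filament
direction, right-handed despite raster y-down), coherence
`(λ₁−λ₂)/(λ₁+λ₂)`.

The pixel mask combines an adaptive Otsu threshold on log tensor energy
with a coherence floor of 0.1. Two failure modes drove this choice: a
fixed low energy quantile floods the mask with shot-noise pixels when
filaments are sparse, while a high quantile combined with a wide tensor
window systematically over-selects regions of mutually parallel
filaments and inflates S of partially aligned networks by ~2–3×.
The adaptive threshold separates the noise floor from structure at any
filament coverage; with it, single-filament orientations are recovered
to < 0.1° and the measured S of phantom ensembles is unbiased.

S is the unweighted pixel mean of `cos 2(θ − θ_axis)` (an
energy-weighted variant exists behind a flag); the cell axis comes from
the eigen-decomposition of the mask's second central moments (+1/12 px²
diagonal regularization; degenerate masks cap the ratio with a
warning). Remaining per-image scatter of S about the ground-truth
`⟨cos 2θ⟩` (±0.1 at 200 crossing filaments) reflects pixel-weighting —
each filament contributes pixels, not one vote — which is inherent to
pixel-based order parameters, on real images as here. Filament phantoms
are straight Gaussian ridges (analytic distance-to-segment profiles —
rasterized anti-aliased lines leave orientation-corrupting staircases)
plus Poisson noise; curvature, branching and 3D tilt are not emulated.

## Morphometry

Contact angles are measured on the sub-pixel (marching-squares)
boundary of the side-view mask within 15 px of the substrate. The
default estimator fits one circle through both near-substrate edge arcs
and takes the tangent angle at the substrate crossing
(`θ = arccos(−z_c/R)`), the droplet-goniometry approach: on a binary
raster the edge moves less than a pixel over a short window, so local
polynomial slopes are quantization-dominated, while the circle fit
recovers 30°–150° phantoms within ±2°. Per-side quadratic-tangent and
secant modes remain for non-circular edges. Colony phantoms are exact
circular segments meeting the substrate at the requested angle; real
colonies are only approximately spherical caps, which the per-side
modes accommodate.

Contact area is exact pixel arithmetic on a binary actin mask
(`n·(pixel/1000)²` µm²); segmentation of rendered images uses a
configurable threshold (Otsu default) plus connected components, and
the threshold rule should be reported with the results. Aspect ratio
delegates to the moment ellipse.

## Studies and statistics

`compare_groups` follows the study recipe: D'Agostino–Pearson omnibus
normality per group (n ≥ 8; smaller groups get NaN with a warning),
then a two-sample Student's t-test (equal variances by default, Welch
by flag), significance at 0.05. No multiple-testing correction is
applied — single pairwise comparisons.

The study runners generate their cohorts at the study's sample sizes
(26 granules or 16 cells per condition) with per-condition generator
parameters (exponent means 0.48/0.11 vs 0.40/0.15, truncated to
(0.05, 1.9); aligned filaments at σ = 8° about the cell axis vs
uniform). Per-granule trajectories use 2^17 samples at 22 kHz and
orientation images 192 px — sizes at which the estimator noise is well
below the biological spread being emulated. Seeds derive
deterministically from the config seed, so identical configs give
byte-identical result tables; config and package version are embedded
in every report. Passing these studies shows the estimators recover the
generating parameters and orderings under the stated noise model — not
that real cells obey that model.

## Repository shape

The package is a library with narrative example scripts; there is no
command-line interface, since every analysis is a few function calls on
in-memory containers and the scripted examples document the workflows.
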