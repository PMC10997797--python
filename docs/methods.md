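# Methods

`edofstain` simulates and trains a dual-channel extended depth-of-field
(EDOF) fluorescence microscope with a pupil phase mask, and renders its
two-channel output as virtual H&E — analytically (Beer-Lambert) and by a
two-step semi-supervised cycle-consistent GAN.  This note records the
models, the parameters that matter, the numerical choices, and what the
synthetic world does and does not establish.

## Image formation

Each fluorescence channel (DAPI-like, 473 nm; Rhodamine-B-like, 640 nm) is
modeled incoherently.  The pupil function is `A(ρ)·exp(i(Φ_DF + Φ_M))` on
the normalized pupil disk; the PSF is the squared magnitude of its Fourier
transform, energy-normalized; the sensor image is the scene convolved with
the depth's PSF, summed over occupied depths, plus i.i.d. Gaussian read
noise (σ = 0.01 on the [0,1] scale) and clipping.

* **Defocus phase** `Φ_DF = (2π/λ) W_m ρ²`.  Two evaluations of the
  path-length error are supported: `exact-z0`, `W_m = (R²/2)(z0−z)/z0²`,
  and the default `paraxial-NA`, `W_m = (NA²/2)(z0−z)`.  The paraxial form
  needs only the published NA (0.13) and DOF (200 µm); the pupil radius
  and in-focus distance of the physical instrument are not published.
  Over the ±100 µm DOF it gives `W_m = ±0.845 µm`, i.e. `(2π/λ)W_m` spans
  ±11.2 rad at 473 nm and ±8.3 rad at 640 nm.  (The corresponding printed
  ranges, ±8.73 and ±11.88 rad, are mutually inconsistent for a shared
  `W_m` — a common `W_m ≈ 0.89 µm` reproduces both magnitudes with the
  channel labels swapped.  We treat this as a configuration note, not a
  target.)
* **Mask phase.**  The mask is a physical height map `h` (µm)
  parameterized by the first 55 Zernike modes (OSA/ANSI ordering =
  complete radial orders 0–9; the ordering convention is ours, the mode
  count is the published one).  Per wavelength,
  `Φ_M = 2π(n(λ)−1)h/λ` with a two-term Cauchy dispersion
  (fused-silica-like, `n = 1.4580 + 0.00354/λ²`); the mask material is not
  published and the constants are configurable.
* **Sampling.**  The pupil is sampled on the frequency grid conjugate to
  the sensor grid, so PSFs come out at the configured object-space pixel
  pitch and apply to scenes by direct FFT convolution (periodic
  boundaries; reflect-padding available for display).  PSFs are cropped
  to a square support and renormalized; an aliasing guard warns when the
  per-pixel pupil-phase step exceeds π.  Full-scale profile: 0.3 µm/px,
  512-pt FFT grid, 128 px support (the ±100 µm defocus blur of a 0.13 NA
  system spans ~87 px at this pitch).  Toy profile: 0.6 µm/px, 384-pt
  grid, 64 px support, 64 px patches.

## Cubic initialization and the two-step schedule

Training step 1 freezes the mask at a cubic wavefront-coding profile
`h ∝ x³ + y³` fitted in the Zernike basis (exact up to quadrature: a cubic
lies within radial order 3).  The published work does not state the cubic
strength; we set the design edge phase α = 20 rad at 473 nm everywhere,
following the standard wavefront-coding operating point of roughly twice
the maximum defocus edge phase (11.2 rad here).

Step 2 trains mask coefficients and network weights jointly.  The
pupil→PSF map is differentiated analytically: for a loss l with
`∂l/∂PSF = h`, the pupil-phase gradient is `−2 Im(P · F[h · conj(U)])`
(with `U = F[P]`), verified against finite differences at 1e-3 relative
tolerance in the test suite.

The digital layer is one encoder–decoder network per channel with skip
connections and a zero-initialized residual head, so the untrained network
is the identity.  Loss is per-channel RMS error, averaged with equal
weights (the weighting is unspecified in the source; equal is ours).
Optimizer is Adam at the published rates for the full-scale profile: 1e-9
(optical) and 1e-4 (digital), 30–40k iterations.

**Toy profile.**  Tests and the scaled-down acceptance analogs use a toy
profile (3–4 resolution levels, width 8, 64² patches, a few thousand
iterations, float32).  Two deliberate departures from the published rates,
chosen for the reduced scale and recorded here:

* `lr_digital = 1e-3` — at 1e-4 the small network does not approach
  convergence within a desk-scale iteration budget.
* `lr_optical` large enough to act (probed at 1e-4–3e-4 µm): with Adam,
  1e-9 µm per step is below float32 resolution and the optical layer would
  be a no-op, which would silence the package's central mechanism (joint
  optics–algorithm optimization).  Joint training measurably improves
  depth consistency: the learned correction reduces the depth-dependent
  lateral translation of the cubic PSF, which is the dominant residual of
  the cubic-only system.

## PSF calibration

Bead stacks (31 depths, 10 µm apart, 5 repeats) are averaged temporally,
background-subtracted (default: image-wide 5th percentile), and the
brightest *isolated* bead is cropped per (channel, depth).  Detection is
connected-component labeling on a lightly smoothed frame at
mean + 5σ; fragments closer than a quarter patch are merged (defocused and
wavefront-coded PSFs have multiple lobes); a bead with any neighbor inside
the crop window is rejected.  The 21 depths covering the target DOF are
selected for fine-tuning, during which the optical layer stays frozen.
Patches are clamped non-negative and normalized to unit sum.  Single-bead
extraction (rather than multi-bead averaging) is a choice; the closed-loop
test recovers generating PSFs at NCC > 0.99 for SNR ≥ 20.

## Beer-Lambert virtual H&E

Per pixel and RGB channel M: `T_M = Π_i exp(−β_{M,i} I_i k)`, with the
nuclear channel in the hematoxylin role and the cytoplasmic channel in the
eosin role; `k = 2.5` for the ×255 export convention.  The β matrix ships
as configuration (hematoxylin ≈ (0.860, 1.000, 0.300), eosin ≈ (0.050,
0.840, 0.544) across R,G,B, following the published channel-integrated
attenuation values of the virtual-transillumination literature) and is
overridable per file; it is not an acceptance-bearing constant.  The
transform is strictly pointwise — no spatial mixing — which is why it
preserves defocus artifacts and can serve as the paired supervision bridge.
No gamma; 8-bit export rounds half-to-even.  Channel intensities are used
raw (an optional percentile stretch exists; the source does not state a
normalization).

## Semi-supervised stain transfer

Generators G (fluorescence→H&E) and F (H&E→fluorescence) train against
patch discriminators with least-squares adversarial losses plus an L1
cycle term weighted by λ1 = 10 (λ1 is unpublished; 10 is the conventional
choice).  No identity-mapping term; no replay buffer; discriminators are
resumed, not re-initialized, in step 2.  Step 1 replaces the H&E domain
with Beer-Lambert renderings of the *same* fluorescence patches, so the
color mapping is learned on exactly co-registered features; step 2 resumes
on unpaired data.  Skipping step 1 requires an explicit flag, because
without the paired pretraining the unpaired objective is free to
hallucinate features.

Published profile: 9 residual blocks at base width 64 with two stride-2
stages, 70×70-receptive-field discriminators, instance norm everywhere,
512² patches, 5 epochs at lr 2e-4.  Toy profile: 3 blocks, width 8, one
stride-2 stage, 34×34 discriminators, 64² patches, lr 1e-3, and the same
5-epoch schedule over ~48 phantom images (the published run is 5 epochs
over 604 images; we scale the dataset, not the epoch count).  The single
stride-2 stage in the toy generator biases the small model toward local
correspondence, which the phantom closed loops (nuclei location assignment,
count agreement) then verify rather than assume.

## Evaluation

* **MS-SSIM**: five scales, 11×11 Gaussian windows (σ 1.5), K1 = 0.01,
  K2 = 0.03, valid-window filtering, 2×2 mean-pool between scales,
  luminance term at the coarsest scale only, conventional five exponents.
  Inputs are converted to luminance first.  Images too small for five
  scales fall back with a warning and renormalized exponents.  No
  installed package provides MS-SSIM; the implementation is cross-checked
  in the tests against an independently coded reference at 1e-4.
* **Resolution**: three-bar targets (bar = gap = line width, length 5×),
  negative-contrast (bright bars); Michelson contrast on the mean profile
  across the central bar length, sampled at bar and gap centers, worse of
  the two orientations; resolved means contrast ≥ 0.1 (the printed results
  use a visual criterion; 0.1 is a repo convention).  The closed-form
  incoherent transfer curve `(2/π)(arccos s − s√(1−s²))` anchors the
  in-focus check: s = 0.5 at 2.46 µm line width for 640 nm / 0.13 NA gives
  0.391.
* **Nuclei counting**: Gaussian smoothing, Otsu threshold,
  distance-transform watershed; for RGB input the nuclear signal comes
  from color deconvolution with the configured β (pseudo-inverse of the
  optical-density mixing matrix).  This replaces the published tool (a
  third-party segmenter); parity with its exact counts is not claimed.
* **Depth sweeps** score each depth's output against the *in-focus output
  of the same system* (the convention of the published depth-consistency
  figure); scoring against ground truth is available as an option.

## What the synthetic world does and does not establish

The generators emulate: feature-rich grayscale pools (multi-scale filtered
noise and blob fields) paired per channel to remove cross-channel
correlation; purely high-frequency texture pools (correlation scales at or
below the diffraction limit, no blob content) for defocus-collapse sweeps;
USAF-style bars; dilute bead monolayers; nuclei/cytoplasm phantoms with
exact ground truth.  They do not model tissue scattering,
stain-uptake variability, illumination falloff, chromatic aberration, or
the appearance statistics of clinical H&E scans.  Green tests therefore
establish the correctness of the computational pipeline and scaled-down
analogs of the published system behavior (depth-invariant resolution,
depth-consistency of the EDOF system vs. collapse of the conventional
one, feature-preserving stain transfer on phantoms) — not clinical imaging
performance.  The full-scale results (30–40k-iteration training, clinical
images, pathologist review) are out of desk-scale reach and are not
claimed.

## Known limitations

* The autodiff engine is CPU/numpy; the published training scale is not
  reproducible with it (by design of the scaled-down profiles).  In
  particular, the desk-scale reconstruction does not restore bar contrast
  at the 2.46 µm line width across the whole DOF (it reaches ~3 µm at all
  depths); the corresponding depth-swept resolution check documents this
  as a failing assertion rather than a relaxed threshold.
* Periodic convolution wraps content at patch borders during training;
  evaluation uses patches large enough that this is immaterial, but very
  small patches would alias structure.
* The learned toy mask inherits the cubic's asymmetric PSF; depth-edge
  MS-SSIM is dominated by its residual lateral shift rather than by blur.
* Beer-Lambert β defaults are literature values, not calibrated to any
  instrument.
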