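# Methods

This note documents the models and numerical choices behind `poremetry`:
what each stage assumes, which parameters matter and why their defaults
are what they are, what the synthetic phantoms do and do not emulate, and
the known limitations.

## Measurement model

A TEM micrograph of a fibrillar hydrogel section is treated as a two-phase
scene: electron-dense alginate fibrils on a cavity background, observed
with additive noise and a slowly varying illumination/staining bias. All
physical lengths derive from a single calibration, the pixel pitch Δ in
nm per pixel side (default 2.34). Note that micrograph calibrations are
sometimes quoted as an area per pixel; this package deliberately takes the
*pitch* as explicit configuration, since all radius classes are lengths.

The quantity of interest is the **relative pore radius (rpr)**: half the
shortest wall-to-wall distance across a cavity. Operationally, rpr at a
skeleton pixel is the exact Euclidean distance-transform (EDT) value there
— the distance to the nearest alginate *pixel center*. The "half the
gap" and "distance to the wall" definitions coincide up to a ±0.5 px
boundary-convention offset; the pixel-center convention is adopted because
it is what the distance transform computes, and every accuracy contract in
the tests carries the corresponding ±0.5 px quantization allowance. A
cavity of one-pixel width therefore has rpr = 1 px, and a slit of width w
has modal rpr = ⌈w/2⌉ px.

**Skeletons** are defined as the local maxima of the EDT within a phase,
thinned to one-pixel width: a pixel belongs to the candidate ridge if its
EDT value is within 0.5 px of the maximum over its 3×3 neighbourhood (the
tolerance absorbs the quantization jitter of exact grid distances along a
center axis), and the ridge is then topologically thinned. Where an
even-width slit leaves two tied center rows, thinning deterministically
keeps the lexicographically first. Any labeled cavity whose ridge was
entirely consumed keeps its EDT-argmax pixel, so every accepted lumen
contributes at least one measurement. This construction degenerates to a
≤5-pixel cluster for a disc (the medial axis of a disc is its center) —
unlike library medial-axis routines, which retain boundary-anchored
spurs — while still tracking the center line of elongated cavities.
Ridge filtering can fragment the axis where a cavity tapers faster than
0.5 px per px; the lost samples are those of intermediate radius within
one cavity, which coarse class binning makes immaterial.

**Frequencies** are per skeleton pixel (one measurement per center-axis
pixel), with radii quantized to 0.01 px before counting, the natural
granularity of exact EDT values. Distributions are percent frequencies
over right-closed classes — rpr: (0,10], (10,20], (20,25], (25,40],
(40,70], (70,∞) nm; flr: multiples of 2.34 nm — so a boundary sample goes
to the lower class ("rpr ≤ 10") and no sample is ever dropped.

## Preprocessing

Order is fixed: inhomogeneity correction → TV denoising → shock filtering.

- **Inhomogeneity correction** subtracts a Gaussian background estimate
  (σ = `background_scale_px`, default 64) and re-centers to the input
  mean. The subtraction is a spatial high-pass implemented in the image
  domain rather than by a frequency cutoff, to avoid ringing at fibril
  edges. The footprint must sit well above the fibril scale (≥ 10× the
  modal fibril width); 64 px removes ≥ 80% of corner-to-corner drift for
  bias fields of correlation length ~200 px on 512²–1024² frames while
  leaving 2–5 px fibrils untouched. Because the output keeps the input's
  global mean, adding a planar ramp shifts the result only by the ramp's
  mean — a constant that subsequent thresholding ignores.
- **TV denoising** uses Chambolle's dual projection algorithm for the
  ROF objective. `tv_weight` is in native intensity units (images are
  processed on their 0–255 scale); the default 18 is calibrated so a flat
  field carrying the default phantom noise (sd 12) loses ≥ 10× its
  variance while a clean two-level step of amplitude 120 keeps its
  amplitude within 10% and its half-maximum crossing within 1 px.
- **Shock filtering** sharpens toward a two-level image: per iteration,
  each pixel moves a step `dt` toward its 3×3 maximum or minimum
  according to the sign of the second directional derivative of a
  Gaussian-smoothed copy (scale `sigma_px`), taken along the dominant
  orientation of the structure tensor (integration scale `rho_px`) — so
  erosion/dilation follows the directed fibril structures. A two-level
  image is an exact fixed point, and `dt` ≤ 0.5 keeps the scheme stable.
  Defaults `sigma_px=1.0`, `rho_px=3.0`, `n_iter=10`, `dt=0.25`: the
  derivative scale must stay below the fibril half-width, otherwise the
  filter erases 2–3 px fibrils (σ=1.5 costs ~3.5 percentage points of
  segmentation accuracy on the default network phantom; σ=1.0 holds
  ~97.5% pixel agreement) while the orientation scale sits above it.
  The dilate/erode branch is discontinuous in the input, so equivariance
  and reproducibility statements hold in bulk rather than for every
  near-tie pixel.

All stages use reflective boundary handling, keeping near-border
measurements defined; each returns a new image with a provenance entry,
never mutating its input.

## Segmentation

Otsu thresholding by default (a fixed threshold is available for
reproducibility across batches). Phase polarity is auto-assigned: the
phase forming the largest 8-connected component is the alginate matrix,
because the matrix is the one connected network; a config override
exists for unusual scenes. Cavities are labeled 4-connected (the standard
complementary pairing with the 8-connected matrix). The minimum lumen
area, default exactly 275.0 nm², is applied as the only morphological
cleanup, with strict `<` for removal after conversion by Δ²: at
Δ = 2.34 nm the pixel cutoff is 275/5.4756 = 50.2 px, so a 50-px lumen
(273.8 nm²) is removed and a 51-px lumen (279.3 nm²) kept. The filter is
idempotent and conserves pixels (removed lumina become matrix).

## Interface profiling

Cell-contour delineation is an input (a binary mask), not an algorithm of
this package. The mask is used in two ways: (i) its pixels are removed
from the matrix before porometry (`exclude_region`), so radii near the
interface are measured to fibril walls only — treating the cell body as a
wall would censor every near-interface sample at its own depth; (ii) the
EDT of the mask complement gives each sample its perpendicular depth
(Euclidean distance to the nearest contour pixel, which for smooth
contours equals the perpendicular distance). Samples at depth 0 (on or
inside the cell) are discarded; depth bins are (lo, hi] in 20 nm steps to
a 400 nm ceiling — bin width chosen at the resolution where near-interface
remodeling is expected to appear, both configurable. Bins with fewer than
30 samples are flagged low-confidence.

**Intrinsic depth censoring.** Interface-referenced porometry is not flat
even in a perfectly uniform matrix: a medial point at depth d cannot carry
a radius greater than d, so the shallowest bins are censored toward small
radii regardless of the material (about +9 percentage points in the ≤10 nm
class within the first 20 nm for the default phantom). Depth effects must
therefore be judged against a matched baseline with the same geometry — a
ground-truth profile of the same scene, or a day-0 image series — rather
than against absolute flatness. `depth_flatness_pvalue` implements this:
replicate-level per-bin class fractions (optionally as paired differences
from a reference profile) are tested against their common mean with a
chi-squared statistic scaled by the *between-replicate standard
deviation*. The sd scale makes the test sensitive to effects a single
image could ever exhibit while ignoring percentage-point-level systematic
measurement artifacts far below any effect of interest; raw pixel-count
contingency tests are unusable here because skeleton samples are strongly
spatially correlated (one cavity contributes many adjacent pixels).

## Physisorption

- **BET**: least-squares fit of x/(n(1−x)) against x = p/p₀ over
  0.05 ≤ x ≤ 0.2 (≥ 3 points required); monolayer capacity from
  slope + intercept; area = n_m·N_A·0.162 nm². A non-positive C constant
  or capacity raises an invalid-fit error carrying the fit diagnostics.
- **BJH** (desorption branch, ≥ 5 points in 0.30–0.995): walking the
  branch from the highest pressure down, each step empties the cores of
  pores whose Kelvin radius falls in the step and thins the film in
  previously emptied pores. Kelvin radius r_k = 2γV_L/(RT ln(p₀/p)) with
  γ = 8.85 mN/m and V_L = 34.68 cm³/mol for N₂ at 77 K; film thickness
  from the Harkins–Jura equation t = 0.1·√(13.99/(0.034 − log₁₀ p)) nm,
  the conventional default for N₂ on oxide-like surfaces (the thickness
  model is pluggable). Core-to-pore conversion assumes cylindrical pores
  (r_p = r_k + t, volume factor (r_p/(r_k+Δt))², film area 2V/r) — the
  standard analyzer output — even though slit-shaped pores are typical
  for these gels; a slit-geometry variant is an extension point, not the
  default. The size *density* dV/dr is reported per step alongside
  incremental volumes so the mode is independent of the pressure grid.
  Comparing BJH volume-percent with image number-percent distributions is
  done as-is, as the standard cross-validation practice does; the two
  weightings agree only when pore volume per class tracks counts, which
  the comparison inherits as a caveat.
- **Units**: isotherm CSVs declare amounts as `mmol/g`, `mol/g` or
  `cm3stp/g` in a `# units:` header; everything is mol/g internally.
- A helper flags hysteretic (type-IV-like) loops when the desorption
  branch exceeds adsorption by > 2% anywhere in 0.4 < p/p₀ < 0.95.

## Synthetic phantoms

The generators provide ground truth for closed-loop validation; realism is
deliberately minimal — they emulate the *artifacts the pipeline corrects*,
not electron optics or alginate chemistry.

- **Geometry**: fibrils are straight thick segments (random orientation,
  uniform position, length uniform on 0.3–1.0 of the canvas diagonal);
  curved fibrils would complicate ground truth without changing what the
  metrology is tested on. Segment centers are drawn from a margin-enlarged
  region so coverage is stationary across the canvas (sampling centers
  only inside the frame thins coverage toward the borders, which would
  masquerade as a depth effect in interface scenes). Density is
  parameterized as centerline length per unit area (default 0.10 px/px²,
  scale-invariant, ~20% alginate area at the default widths); nominal
  widths default to 2–5 px with probabilities (0.50, 0.30, 0.15, 0.05),
  which reproduces the small-gap-dominated cavity statistics of hydrogel
  sections (≈ half the truth rpr at or below 10 nm) and fibril radii
  dominated by the first two 2.34 nm classes.
- **Ground-truth gaps** are 2× the nearest-wall distance at cavity medial
  points — the same quantity the pipeline estimates — computed through an
  independent route (KD-tree nearest-neighbour search against wall
  pixels, not the grid EDT); a scanline run-length oracle cross-checks
  rectilinear phantoms. Truth and measurement therefore share the
  definition but not the implementation.
- **Rendering**: alginate dark (60) on bright cavities (180), additive
  Gaussian noise (default sd 12), plus an additive bias field — heavily
  smoothed seeded noise rescaled to a target amplitude (default 20) and
  correlation scale (default 200 px) — clipped to [0, 255]. Zero noise
  and zero amplitude reproduce the two-level image exactly. Not emulated:
  shot-noise statistics, staining granularity, astigmatism, section
  thickness effects; passing closed-loop tests demonstrates correctness
  of the measurement chain under controlled corruption, not performance
  on arbitrary real micrographs.
- **Cell scenes**: a solid disc cell with the fibril network around it;
  with a nonzero halo boost, short fibrils are added inside the halo ring
  (default depth 40 nm) until the truth-mask near-field small-pore
  fraction exceeds the far field by the requested boost — the recorded
  near/far ground truth is then measured on the final mask, so recovery
  tests remain closed-loop. Truth zones use the same open-cell definition
  as the measurement protocol.
- **Isotherms**: the BET generator inverts the target surface area to a
  monolayer capacity and evaluates the two-parameter BET equation
  (optional multiplicative noise); 245 and 532 m²/g are realistic preset
  magnitudes for 0.8% and 1.4% w/v alginate capsules. The mesopore
  generator forward-models a bundle of cylindrical pores through the same
  Kelvin + film model the BJH inversion uses (condensation at r_k + t on
  desorption, at the cylindrical-sleeve radius r_k/2 + t on adsorption,
  producing a type-IV/H3-style loop); its pressure grid densifies toward
  saturation as analyzer schedules do. Sharing the thermodynamic model
  between forward and inverse means the closed loop validates the BJH
  recursion bookkeeping (volume/film/area accounting, grid handling), not
  the Kelvin model itself.

## Problem sizes and tolerances

Validation runs use 512² phantoms for routine closed loops and one 1024²
network for distribution recovery (total-variation distance ≤ 0.15 against
truth; measured ≈ 0.02), slits of 3–15 px, 5 replicate seeds for effect
detection and 10 for no-effect controls, and 60–80-point isotherms —
sizes at which every contract is comfortably exercised on a laptop-class
machine in about a minute each for the test suite and the acceptance
script. Closed-loop accuracy contracts: slit modal rpr within ±0.5 px;
segmentation pixel agreement ≥ 95% (measured ≈ 97.5%); BET recovery
within 0.5% noiseless and 3% mean error at 2% noise; BJH modal radius
within 10%; halo boost estimate within ±0.1 of truth.

## Limitations

- 2-D section metrology: no stereological correction to 3-D pore sizes;
  the cross-validation against physisorption is a consistency check
  between two operational definitions, not a 3-D reconstruction.
- The rpr of cavities wider than they are deep is bounded by the section,
  and near-interface bins are intrinsically censored (see above).
- Phantom realism is minimal by design; thresholding-based segmentation
  assumes a bimodal intensity scene and will degrade on micrographs with
  strong texture inside either phase.
- BJH assumes cylindrical pores and open mesopores in 0.3 ≤ p/p₀ ≤ 0.995;
  micropore analysis (t-plot, DFT) is out of scope.
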