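# poremetry

Pore-size-distribution metrology for hydrogel matrices imaged by
transmission electron microscopy, with nitrogen-physisorption
cross-validation.

Hydrogels such as calcium-alginate form networks of fibril-like structures
whose cavities ("relative pores") control nutrient and protein diffusion
around encapsulated cells. Classical porosimetry (mercury intrusion, gas
sorption) cannot be applied with cells present and says nothing about how a
growing cell remodels the matrix at its surface. `poremetry` implements an
image-analysis route: from a calibrated 2-D TEM micrograph it measures the
distribution of relative pore radii, the fibril radii, and — given a
delineated cell contour — how the pore population changes with
perpendicular distance from the cell-biomaterial interface.

## Method

For a micrograph with pixel pitch Δ (nm/px, default 2.34):

1. **Conditioning** — high-pass inhomogeneity correction (subtraction of a
   large-footprint Gaussian background), edge-preserving total-variation
   (ROF) denoising, and coherence-enhancing shock filtering that sharpens
   the directed fibril structures toward a two-level image.
2. **Segmentation** — Otsu thresholding into alginate and cavity phases
   (polarity auto-detected: the matrix is the phase with the largest
   connected component); cavities smaller than 275 nm² are discarded.
3. **Porometry** — exact Euclidean distance transform *D(x)* of the cavity
   phase; a one-pixel-wide skeleton through the local maxima of *D*; one
   sample per skeleton pixel. The relative pore radius is
   `rpr = D(x)·Δ` — half the wall-to-wall gap across the cavity. The same
   measurement on the inverted mask yields fibril-like radii (flr).
   Samples are aggregated into percent-frequency distributions over the
   standard classes (rpr: ≤10, 10–20, 20–25, 25–40, 40–70, >70 nm;
   flr: multiples of 2.34 nm).
4. **Interface profiling** — each rpr sample is assigned the Euclidean
   distance of its skeleton pixel from a supplied cell-contour mask and
   profiled in 20 nm depth bins up to 400 nm. The cell body is excluded
   from the matrix, so radii are measured to fibril walls only.
5. **Physisorption** — BET specific surface area from the linearized
   multilayer-adsorption equation over relative pressure 0.05–0.2
   (0.162 nm² per N₂ molecule), and a BJH mesopore size distribution from
   the desorption branch (Kelvin equation + Harkins–Jura film thickness,
   cylindrical-pore correction), binnable on the same radius classes as the
   image-derived distribution for a per-bin comparison.

Every stage is validated closed-loop on synthetic phantoms with known
ground truth (slits, discs, random fibril networks, cell-with-halo scenes,
forward-modeled isotherms); see `docs/methods.md` for the models,
parameters and their rationale.

## Worked example

Generate a rendered fibril-network phantom (noise, illumination bias) and
measure it:

```sh
poremetry fixtures --kind network --size-px 512 --seed 11 --out-dir demo
poremetry porometry demo/rendered.tif --out-dir demo_out
```

prints

```
pooled over 12133 samples (1 images, 0 failed)
           <= 10 nm :   59.8 %
         10 - 20 nm :   24.4 %
         20 - 25 nm :    5.9 %
         25 - 40 nm :    8.1 %
         40 - 70 nm :    1.7 %
            > 70 nm :    0.0 %
```

i.e. ~60% of the measured pore radii fall at or below 10 nm — for this
phantom the ground-truth distribution recorded in `demo/truth.json` bins to
(58.2, 25.2, 6.3, 8.3, 2.0, 0.0)%, so the full pipeline recovers the truth
within ~2 percentage points per class despite the simulated noise and
contrast drift. Percentages are per skeleton-pixel measurement; `demo_out/`
holds the same numbers as JSON/CSV plus a bar chart.

The other subcommands follow the same pattern: `poremetry interface`
(depth profiles against a cell mask), `poremetry physisorption`
(BET + BJH from an isotherm CSV), `poremetry compare` (per-bin discrepancy
of two binned distributions).

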