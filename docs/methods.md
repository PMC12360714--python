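# Methods

This note documents the models, algorithms, parameter choices, and known
limitations behind `phantomqa`.

## Synthetic phantom scenes

The renderer (`phantomqa.scene`) produces images of three physical
targets under a parametric forward model:

```
image = noise( PSF * ( Σ_wells  peak · rel_i · I(x_i) · disk_i ) + b )
```

* **Dot grid** — a square lattice of equal wells, default 1 mm diameter at
  2 mm pitch over 100 × 100 mm (51 × 51 = 2601 wells), rendered at
  0.1 mm/px into a 1024 × 1024 frame by default.
* **Dilution target** — 3 × 3 wells whose relative signal is
  `(c / c_max)^m_true`, with exactly one 0 nM control. The default
  concentration series {0, 1, 3, 10, 30, 60, 100, 300, 1000} nM is a
  fixture choice: the physical target spans 0–1000 nM and the package does
  not assume any particular intermediate steps.
* **Cylinders** — two Ø10 mm disks side by side, signal linear in
  concentration.

Model assumptions, each of which is also what the analyses assume:

* **Illumination** `I(x)` multiplies the *signal* only and is evaluated at
  the (distorted) well center; it is normalized to a maximum of 1 over the
  frame and must be strictly positive. Available shapes: uniform, radial
  Gaussian (default falloff chosen so efficiency drops by roughly 40% at
  ~50 mm off-axis, a realistic open-field illumination), separable
  polynomial, and tabulated grids.
* **Background** `b` is additive and spatially constant. This is the
  crucial asymmetry that makes flat-field correction misbehave: gain maps
  derived from fluorescent signal divide the background too.
* **Distortion** is a Brown radial polynomial
  `r' = r (1 + k1·rn² + k2·rn⁴)` (radius normalized by half the image
  diagonal) composed with a projective keystone map from tilting the
  object plane about the horizontal axis through the principal point
  (effective focal length: one image diagonal). `k1 < 0` is barrel. The
  map is validated to be invertible over the frame.
* **PSF** is an isotropic Gaussian (default σ = 1.5 px); **noise** is
  Gaussian (`gaussian`) or Gaussian with variance proportional to signal
  (`poisson_like`), avoiding integer-count coupling to bit depth.

Wells are drawn as anti-aliased disks via 4 × 4 sub-pixel coverage
sampling; with a fixed seed the render is bit-identical. Ground truth
records each well's distorted and undistorted center, the illumination at
the center, and the signal amplitude.

What the simulator does **not** emulate: fixed-pattern sensor noise,
vignetting separate from illumination, spectral effects, photobleaching,
fluorophore self-quenching, non-planar targets, and the detection
threshold floor of real cameras. Tests passing on these scenes therefore
validate the *analysis chain* — they do not certify behavior on data with
those additional effects.

## Well detection

Detection thresholds the image (Otsu by default — parameter-free and
invariant to overall gain; fixed and quantile thresholds available),
labels 8-connected components, and filters by area (default minimum: 25%
of the nominal well footprint, or 5 px when the scale is unknown) and by a
2 px border margin, since components touching the frame have biased
centroids.

Two measurement choices matter for accuracy and are worth recording:

* **Centroid**: intensity-weighted with weights equal to intensity *in
  excess of the threshold*. Weights then fall continuously to zero at the
  component boundary; weighting by raw intensity over a hard-truncated
  component carries a sub-pixel phase bias of up to ~0.15 px for small
  blurred wells, an order of magnitude above this scheme.
* **Mean intensity**: by default the mean over a *half-diameter disk ROI*
  centered on the centroid (the same ROI rule used for the dilution
  target, scaled to the dot grid). A component mean is also offered, but
  with a global threshold over a nonuniform field the component of a dim
  well retains a different share of its blurred edge than a bright well's,
  biasing the intensity sample by tens of percent; the plateau ROI is
  insensitive to this.

Coordinates are 0-based with pixel centers on integers, x right, y down.

## Uniformity surfaces

Samples from one or more images of the moving target are pooled in the
fixed camera frame — "stitching" is pooling, no registration — and samples
closer than 1 px across images are treated as the same well re-imaged and
averaged. Two fits:

* **b-spline** (default): bicubic FITPACK smoothing spline. The smoothing
  budget `s` is chosen by 3-fold cross-validation over a log grid spanning
  `n·var(z)·[1e-7, 1]`; for pools above 3000 samples CV runs on a random
  3000-sample subset and the chosen `s` is rescaled in proportion to the
  sample count (FITPACK's `s` is an absolute residual budget). FITPACK can
  fail quietly at small `s` on scattered data (an `ier` warning alongside
  a garbage surface); such fits are rejected and the final fit escalates
  `s` tenfold until sound.
* **RBF**: thin-plate-spline interpolation with a small ridge term
  (default `1e-6 · n` on max-normalized intensities), switching to local
  64-neighbor interpolation above 2000 samples for tractability. Slower
  and noise-sensitive, but preserves sharp illumination structure the
  b-spline smooths away.

The surface is evaluated on a 129 × 129 lattice, normalized by the fitted
maximum over the valid region (so a noisy sample cannot set the scale),
clipped to [0, 1], and masked to the convex hull of the samples —
spline/RBF extrapolation beyond the data is unreliable and refused unless
explicitly requested. Iso-maps report the fraction of the valid region at
or above each threshold (default 0.60/0.80/0.90/0.95, strictly
increasing); masks are nested by construction. Line profiles sample full
rows/columns at fractional frame positions (quarters by default).

## Reference grid and distortion

The reference lattice is anchored at the detected well nearest the image
center (`((W−1)/2, (H−1)/2)`), on the standard dot-target premise that
distortion is negligible at the center. Estimation proceeds in three
steps: (1) initial pitch and orientation from nearest-neighbor
displacement vectors of wells inside the central window (a disk of
diameter 20% of the image diagonal; at least 9 wells required), with
angles folded modulo 90°; (2) a least-squares lattice fit of integer
indices to positions over the central window, anchor held fixed;
(3) a scale refinement using only the first two lattice rings around the
anchor. Step (3) matters: nearest-neighbor spacing at radius r is
stretched by the *derivative* of the radial map (≈ `1 + 3·k1·rn²`), so a
window-wide average inherits a scale bias of order 0.1% at `k1 = −0.05`,
enough to corrupt a sub-0.1% distortion measurement; the innermost rings
reduce this bias by two orders of magnitude.

Matching grows outward from the anchor in lattice index space. Each
lattice point's prediction is corrected by the mean offset of its already
matched 4-neighbors before the nearest-unclaimed-well search, with a
tolerance of 0.5 pitch around the corrected prediction. Because distortion
is smooth, neighbor-relative displacements stay well under half a pitch
even when the cumulative displacement of outer wells exceeds a full pitch
(at `k1 = −0.05` the corner wells move ~1.7 pitches); naive
nearest-ideal-point matching would alias there. Spurious detections
between lattice sites exceed the tolerance and are reported unmatched.

Distortion per well applies the actual/expected distance formula exactly;
the central well (expected distance 0) carries no value. The
barrel/pincushion label is the sign of the mean distortion over the outer
half of the radial range (|mean| below 0.02 pp reports "none"). Keystone
asymmetry reports mean distortion per half-plane and the left−right and
top−bottom differentials; radially symmetric distortion gives near-zero
differentials, a tilted plane splits one axis's sign, and flipping the
tilt flips the differential.

Multi-image analysis processes each image independently (each must satisfy
the central-well minimum) and concatenates records. The tool reports
distortion; it does not undistort images or certify against dot-target
standards, whose strict alignment and dot-size conditions are not
enforced.

## Flat-field correction

The correction map is the reciprocal of the normalized profile, bilinearly
upsampled from the evaluation lattice to the pixel frame. Profile values
below a floor (default 0.05, i.e. gain capped at 20×) are clamped and
counted — unbounded gain at the unilluminated frame edge would otherwise
dominate any corrected image; the clamp count keeps artifact analyses
honest. Pixels outside the valid region pass through with unit gain and a
cleared mask bit; optionally the valid region can be extended by a few
pixels of nearest-valid gain (`edge_fill_px`) so the outer halves of wells
sitting exactly on the sample hull are corrected consistently. Correction
operates on float counts; quantization and saturation happen only at
image export.

The package deliberately implements only the single-component
multiplicative correction. Its characteristic failure is structural, not
numerical: the profile is proportional to `signal·I + b`, so dividing by
it maps a pure-background region to `b / I > b` — corrected background
*rises* toward the field edge. Two-component (background-subtracted) and
hybrid reference-scaling corrections are out of scope.

## Concentration linearity

Wells are measured with disk ROIs of half the well diameter, baselined by
subtracting the 0 nM control mean (removing any shared additive offset
exactly), and normalized to the maximum *included* baselined value —
exclusions are applied first, and the order is fixed. Wells with
non-positive baselined intensity cannot enter a log fit and are excluded
with a recorded reason (after correction the amplified control can
overshoot the dimmest wells, which is exactly the artifact under study).
The fit is unweighted ordinary least squares of `log10(normalized)` on
`log10(concentration)`; the slope is `m`, the intercept `C`, and at least
3 usable wells are required. OLS in log space was chosen because the
quantity of interest is the exponent, not a calibration curve; weighting
schemes would change `m` only at the noise level of the ROI means.

## Problem sizes and numerical choices

* Default dot-grid scenes run at 1024 px / 0.1 mm/px (5 px well radius);
  the flat-field round-trip experiment runs 16 images at 512 px /
  0.22 mm/px, which preserves ≥ 4.5 px well diameters while keeping the
  whole experiment under a minute.
* The round trip uses the RBF profile (as the correction source) and the
  b-spline for the post-correction refit, so high-frequency structure is
  corrected but the flatness verdict is not dominated by refit noise.
* Cross-validation fold assignment and CV subsampling use fixed internal
  seeds: they are model selection, not simulation, and must not change
  between runs of the same data.
* Degenerate inputs are rejected loudly: overlapping wells, wells under
  2 px across, scenes with no well in frame, non-invertible distortion,
  non-positive illumination, rank-deficient sample geometry, fewer than 9
  central wells, clipped ROIs.
* A disk ROI whose radius captures no pixel center falls back to the
  single nearest pixel rather than returning an empty mean.

## Known limitations

* The reference grid assumes a near-square lattice (basis lengths within
  25%); strongly anisotropic optics would need a generalized lattice fit.
* Matching propagates from the center; a wide annulus of missing wells
  can strand the region beyond it (reported as unmatched, never silently
  mismatched).
* The RBF's local-neighbor mode trades global smoothness for speed on
  large pools; with very noisy data the b-spline profile is the safer
  correction source.
* Iso-map fractions are computed on the evaluation lattice (129 × 129 by
  default); their resolution is the lattice cell, about 0.8% of the frame
  per axis.
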