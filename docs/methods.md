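# Methods

This note documents the models, conventions and numerical choices behind
`gelscope`, what its synthetic data do and do not emulate, and the known
limitations.

## Coordinates, units and metadata

Coordinates are `(row, col)`, 0-based, with pixel centers at integer
positions.  Physical distances are pixel distances times
`pixel_size_um`; quantities reported "pre-expansion" are additionally
divided by the `expansion_fold` annotation carried on every
`MultiplexImage`.  This is the single conversion point in the package:
rescaling an image by a known fold multiplies its `expansion_fold` and
leaves `pixel_size_um` (an instrument property) untouched, so line-scan
positions and distortion curves in tissue coordinates come out right by
construction.

Channels are ion counts per pixel: non-negative, NaN-free, and treated
as Poisson-distributed where noise matters.  Readers reject NaN or
negative pixels rather than propagate them.

## Preprocessing

**Percentile capping** clips each channel at its own q-th percentile
(default 99.7), the standard guard against hot pixels before
segmentation or display.  All percentiles in the package use numpy's
linear interpolation between order statistics; test oracles share this
convention.  Capping is idempotent up to the vanishing shift caused by
the ties it creates at the cap.

**dsDNA tile normalisation** divides every channel by the median of the
tile's *nonzero* dsDNA pixels.  Count channels are zero-inflated, so a
median over all pixels would frequently be zero; restricting to nonzero
pixels keeps the divisor meaningful while preserving the intent of a
per-tile sensitivity reference.  The operation makes downstream
anchoring profiles exactly invariant to a global rescaling of a tile's
channels.

**Feature segmentation** of non-nuclear structures (vessels, astrocyte
and microglia territories) runs on weighted composite channels (e.g.
GLUT1 + vWF + Fibrinogen for vessels) through a fully specified chain:
Gaussian blur → threshold (Otsu or absolute) → morphological closing →
8-connected components → minimum-size filter, with labels numbered
consecutively in raster order of each object's first pixel.  With the
Otsu option the chain is invariant to positive rescaling of the
composite.  Deep-learning nuclear/whole-cell segmentation is out of
scope; externally produced cell masks are accepted as inputs.

**Phenotyping** is a deliberately simple argmax over summed class-marker
signals (ties to the first declared class; zero signal left unassigned).
It is plumbing for the class-fraction machinery, not a substitute for
clustering-based phenotyping.

## Anchoring (perivascular step-ring profiling)

Each vessel object is decomposed into 1-pixel rings:
`ring(+k) = D_k \ D_{k-1}` outward and `ring(-k) = E_{k-1} \ E_k`
inward, where `D_k`/`E_k` are k-fold unit dilations/erosions by the
structuring element and `D_0 = E_0` is the object.  Choices that matter:

- **Structuring element**: 3×3 square by default (configurable), so the
  step index equals the chessboard distance from the object boundary.
  Test oracles use the chessboard distance transform and must match the
  element exactly.
- **Step 0 is not a ring**: the boundary pixels belong to step −1 (the
  first erosion shell).  A marker layer sitting exactly on the boundary
  therefore peaks at −1 or +1, never 0.
- **Overlap exclusion**: ring pixels falling inside any *other* object's
  original mask are removed, so neighbouring vessels do not contaminate
  the outward steps.
- **Border exclusion**: objects whose `k_max`-fold dilation would leave
  the image are excluded by default, so truncated outer rings do not
  bias the aggregate.
- **Aggregation**: per-object ring means are averaged across objects
  (not pooled by pixel), matching a per-vessel profiling design; the CI
  is the normal approximation mean ± 1.96·SD/√n across objects (a
  Student-t mode is available), undefined below n = 2.  Empty rings
  contribute missing values, not zeros.
- **Transform order**: the optional square-root transform is applied to
  each object's channel values before averaging; z-normalisation then
  standardises the aggregated means across steps (population SD).  The
  sqrt is applied to channel intensities only — class pixel fractions
  are already on [0, 1] and are aggregated untransformed.
- **Peaks**: per channel, the argmax of the z-vector, ties broken toward
  the lumen (most negative step).  Channels constant across steps are
  flagged and excluded rather than given arbitrary peaks.

Default step ranges: −40…+20 for expanded acquisitions (whose pixels are
~4× finer in tissue coordinates) and −10…+5 for unexpanded ones.

## Expansion-fold estimators

*Linear*: every unordered pair of matched landmarks contributes a
post/pre physical distance ratio; the estimate is the mean ratio and its
SD (coincident pre-landmarks are skipped with a warning).  *Area*:
√(physical area ratio) of the tissue footprints.  *Segmentation*:
√(ratio of a cell-area statistic), median by default for robustness to
segmentation tails, with a configurable minimum cell count (20).  Both
area-based estimators take the square root so all three report a
*linear* fold on one comparable axis.

## Line scans and the 16–84% criterion

Line profiles are sampled at unit-pixel spacing with bilinear
interpolation (nearest behind a flag); positions are reported in
pre-expansion micrometres.  The resolution estimator assumes a single
monotone edge between two plateaus: plateaus are the means of the first
and last 10% of samples (configurable), the 16% and 84% crossings are
located by linear interpolation, and their separation is the resolution.
A profile that crosses the mid-level more or fewer than once is rejected
with a named error.  The estimator is exactly invariant to affine
intensity transforms of the profile; for a Gaussian-blurred edge it
returns 2σ (the 16th/84th normal quantiles sit at ∓1σ), and for a linear
ramp of length L it returns 0.68·L.

## Distortion quantification

Background is removed by a rolling-ball subtraction implemented as
grayscale morphological opening with an exact flat disk footprint
(default radius 50 px).  Landmarks are local maxima of the smoothed
image above a relative threshold, greedily thinned to a minimum spacing
in descending-intensity order.

Registration is a self-contained two-stage estimator with the contract:
the affine stage removes global pose and scale, the nonrigid stage
supplies dense correspondence.  The affine (y = Mx + t, fixed → moving)
is initialised by phase correlation and refined by Powell minimisation
of the mean squared intensity difference over a 4×/2×/1× resolution
pyramid; failure to reduce the loss raises a diagnostic error.  The
nonrigid stage iteratively block-matches windows around a control grid
(phase correlation with subpixel upsampling), spline-interpolates the
offsets to a dense displacement field, re-corrects and repeats; its
fixed point is the exact forward displacement of the image content.  An
externally computed displacement field can be supplied in place of
estimation (two-plane 32-bit TIFF exchange format).

The distortion curve bins every unordered landmark pair by its
pre-image physical distance L (default 12.15 µm × 100 bins) and reports
per-bin RMS of |L − L′|, where L′ is the distance after mapping the
landmarks through the residual nonrigid field (the affine having removed
global scale/rotation).  Landmarks closer to the border than the control
spacing are dropped — the estimated field is unsupported outside the
control grid.  When a synthetic pair shares a mount (no true global
transform), the fitted affine absorbs part of the generated field's
smooth trend; composing it back into the mapped positions
(`include_affine=True`) makes the estimated curve commensurable with one
computed from the raw ground-truth field.  Replicate curves aggregate
per bin as mean ± SD, with a replicate's empty bins excluded from that
bin.

Validation thresholds for the recovery experiments exclude bins whose
centre length is below the nonrigid control spacing (lengths beneath the
estimator's resolvable scale) or whose pair support is sparse; the
analytic scaling law RMS ≈ ε·L is likewise checked only where the bin
width is small relative to L, since the within-bin spread of L dominates
the comparison in the first few bins.

## Gradients along tissue strips

Per-channel counts are summed perpendicular to the strip's long axis,
min-max normalised between the channel's 5% and 95% quantiles (values
outside [0, 1] are kept, not clipped; a channel constant between its
quantiles is an error), and averaged in windows of 200 positions sliding
by 50.  The 95% CI is computed across the positions within each window;
a replicate-across-tiles mode is the natural extension but the
within-window CI is the default because no replicate structure is
assumed.

## Synthetic phantoms: what they emulate, and what they do not

The generators are pure functions of (specification, seed):

- **Vessel phantoms**: circular cross-sections (lumen disc dilated by a
  wall thickness) carrying concentric marker layers defined as bands of
  the signed boundary distance — Euclidean by default, or chessboard,
  the metric induced by the 3×3 ring element.  Layer offsets are free
  parameters: the radial layout of real perivascular architecture is not
  calibrated quantitatively here, only its ordered, layered structure.
  A layer defined in the chessboard metric lands on exact ring indices,
  which is what makes exact step recovery a meaningful test; in the
  Euclidean metric the discrete ring geometry smears a layer over
  neighbouring steps and only the ordering is exactly recoverable.
- **Cell fields**: circular nuclei with lognormal areas (given mean and
  CV) placed by rejection sampling with bounded retries; nuclear
  channels are positive exactly on cell pixels before noise.
- **Noise**: pure pixelwise Poisson on expected counts — no detector
  dead-time, beam drift, or channel crosstalk.
- **Scaling**: `apply_scale` resizes by a known fold (bilinear for
  intensities, nearest for masks, which preserves label identities) and
  updates the expansion-fold annotation.
- **Warps**: random control-grid offsets spline-interpolated to a dense
  C1 field, rescaled so the maximum displacement equals the requested
  amplitude.  `apply_warp` resamples by reverse mapping;
  `displace_points` maps landmarks forward, consistent to first order
  for the smooth, small-amplitude fields used.

Passing tests on these phantoms therefore demonstrate correctness of the
measurement machinery under the stated statistical model — isotropic
geometry, Poisson counts, smooth distortions — not robustness to
staining artefacts, segmentation errors on real morphology, tile
stitching seams, or instrument drift, none of which the generators
simulate.  Vessels are single circular discs; elongated vessels and 3-D
volumes are out of scope.

## Benchmark problem sizes

The self-validation experiments run at sizes chosen to keep the full
suite fast while leaving the statistics well-resolved: 120-cell fields
(220² px) rescaled up to 4.5×; 30 vessels of object radius 16 px on a
288×344 grid with layers at (−10, 0, +3, +8) px and amplitude 60
counts; 256² textures with warp amplitudes 1–5 px on a 64 px control
grid; 150 landmarks for the scaling-law curve; and 200 replicates of 30
objects for CI coverage (nominal 95%, normal-approximation CIs across 30
objects give ~94% in expectation).

## Known limitations

- The registration is a simplified SSD optimizer: adequate for
  mono-modal, mildly deformed pairs, not a general-purpose replacement
  for production registration toolchains; the external-field escape
  hatch exists for exactly that reason.
- Ring decomposition on a pixel grid cannot represent Euclidean radial
  distance exactly; with the square element, step index is chessboard
  distance, and peak positions of Euclidean-defined structures can shift
  by a step or two even noise-free.
- The argmax phenotyper ignores marker covariance and intensity
  calibration; class fractions downstream inherit its simplicity.
- Statistical comparison between sample groups (e.g. diseased vs
  control cohorts) is out of scope; the package produces the per-sample
  profiles such a comparison would consume.
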