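# gelscope

QC metrics and perivascular spatial profiling for expansion-gel
multiplexed ion-beam and mass-cytometry imaging (MIBI / IMC).

Hydrogel expansion physically magnifies a tissue section by a linear
factor *s* (~3.7× in practice) before mass-spectrometry imaging, pushing
antibody-based imaging below the instrument's native spot size.  Getting
trustworthy biology out of an expanded acquisition requires a set of
quantitative checks and measurements that this package implements as a
tested, reusable library:

- **Expansion-fold estimation** by three independent strategies —
  landmark distance ratios (*linear*), tissue footprint
  (*area*: s = √(A′/A)), and cell-size distributions (*segmentation*:
  s = √(ã′/ã) for a size statistic ã) — which must agree on an
  isotropically expanded sample.
- **Resolution** from line scans across a single edge by the 16–84%
  criterion: the distance over which the edge-spread profile rises from
  16% to 84% of its amplitude, which equals 2σ for a Gaussian-blurred
  edge.
- **Distortion** between paired images (pre/post compression or
  remounting): affine + nonrigid registration, then the RMS of pairwise
  landmark-distance changes |L − L′| binned by measurement length L
  (12.15 µm bins × 100 by default).
- **Perivascular "anchoring" profiling**, the core spatial analysis:
  each segmented vessel object is decomposed into 1-pixel morphological
  step rings — ring(+k) = D_k \ D_{k−1} outward, ring(−k) = E_{k−1} \ E_k
  inward, with D/E unit dilations/erosions — and each ring yields
  per-marker mean counts and per-phenotype pixel fractions.  Profiles are
  averaged across vessels with 95% CIs (mean ± 1.96·SD/√n), square-root
  transformed for display, z-normalised across steps, and summarised by
  each marker's radial peak step.  The peak ordering reads out the
  layered architecture of structures such as the blood–brain barrier
  (endothelium → basement membrane → astrocyte end-feet).
- **Marker gradients** along long tissue strips: perpendicular sums,
  5%/95% quantile min-max normalisation, and 200-px windows sliding by
  50 px with 95% CIs.
- **Synthetic phantoms** with known ground truth — vessels with
  concentric marker layers at known signed radial offsets, packed nuclear
  fields, Poisson ion-count noise, known rescaling, and smooth bounded
  warp fields — so every estimator above can be validated end to end.

## Worked example

Profile the radial organisation of markers around synthetic vessels with
a known layered ground truth:

```python
import gelscope as g

spec = g.PhantomSpec(
    width_px=220, height_px=220, pixel_size_um=0.39,
    vessels=[g.Vessel((70, 70), 9, 5), g.Vessel((150, 150), 9, 5)],
    layers=[
        g.Layer("CD31", -4.0, 2.0, 70.0),       # endothelium, inside the wall
        g.Layer("GLUT1", 0.0, 2.0, 80.0),       # vessel boundary
        g.Layer("CollagenIV", 3.0, 2.0, 60.0),  # basement membrane, outside
        g.Layer("dsDNA", -8.0, 4.0, 90.0),      # nuclei toward the lumen
    ],
    background_rate=0.5, seed=11,
)
image, vessel_mask, truth = g.make_vessel_phantom(spec, noise=True)
image = g.normalize_tile_by_dsdna(image, "dsDNA")     # per-tile normalisation
result = g.anchor_vessels(image, vessel_mask, k_min=-10, k_max=8)
print(result.summary())
```

prints

```
Anchoring analysis over 2 objects (0 excluded at border)
transform=sqrt, ci=normal
peak steps (innermost first):
  dsDNA: -7
  CD31: -3
  GLUT1: -1
  CollagenIV: +2
```

Each peak step is the signed ring index (negative = inside the vessel
object, in pixels from its boundary) where that marker's z-normalised
radial profile is maximal.  The recovered ordering
dsDNA → CD31 → GLUT1 → CollagenIV matches the generative layer offsets
(−8, −4, 0, +3); Poisson noise and the discrete ring geometry shift each
peak by at most one step.  `result.profile.stats` holds the per-step
mean/SD/CI table and `result.peaks.z` the z-normalised heatmap matrix.

A command-line surface wraps the same library
(`gelscope simulate | segment | anchor | fold | resolution | distort |
gradient`); run `gelscope --help` for the subcommands.

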