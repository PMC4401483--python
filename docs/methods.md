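# Methods

This note documents the models, conventions, parameter choices and known
limitations behind `slitfundus`, in the spirit of a package manual's
"statistical/optical model" chapter.

## Lens magnification model

A hand-held converging lens of power *P* (diopters) in front of an
emmetropic schematic eye forms an aerial image of the fundus with
transverse magnification *m* = aerial size / retinal size. The three
standard lenses carry manufacturer values

| power | m | field of a 3.5 mm stop |
|---|---|---|
| +90 D | 0.75 | 4.67 mm (reported 4.7) |
| +60 D | 1.15 | 3.04 mm (commonly quoted 3.1) |
| +40 D | 1.67 | 2.10 mm (reported 2.1) |

The two directions of the projection are exact inverses: an aperture of
diameter *a* illuminates *a/m* on the retina, and a retinal feature of size
*s* appears at *m·s* in the aerial plane. On-screen metrology therefore
divides the calibrated aerial length by *m* (`retinal_length`); areas scale
with 1/*m*². The +60 D field computes to 3.5/1.15 = 3.04 mm while 3.1 mm is
the commonly quoted figure — a ≈ 2 % discrepancy whose rounding provenance
is unclear; the toolkit always reports the computed value.

Reported millimetre values are rounded to one decimal, half away from zero
(`round_mm`), matching the conventional presentation of these diameters.

**Off-catalog powers.** The catalog factors are close to reciprocal in
power (the product (1/m)/P varies by < 6 % across the triple), so unknown
powers use 1/m = P/c with c ≈ 67.8 fitted by least squares (regression of
1/m on P through the origin). Residuals at the three catalog points are
0.5–1.7 %, within a 3 % band. Fitted values carry `catalog=False` so
reports can distinguish printed from modelled magnification.

**Drawback distance.** Focusing the aerial image requires retreating the
slit lamp relative to anterior-segment focus. Quoted values (3, 4, 6,
10 cm at +90/+60/+40/+20 D) are returned verbatim; intermediate powers use
the affine-in-focal-length fit d ≈ 2f + 9 mm (f = 1000/P mm), which
reproduces the 90/60/40 D anchors within 0.5 cm and respects the "over
10 cm" character of the +20 D value (it gives 10.9 cm). Fitted values are
flagged.

**Ametropia.** An uncorrected refractive error R (spherical equivalent, D)
changes effective magnification. The toolkit applies the first-order
vergence ratio `factor = P / (P − R)`: exactly 1 for emmetropia, > 1
(higher magnification) for hyperopes, < 1 for myopes, antisymmetric to
first order, and shrinking in deviation as lens power grows. Only the sign
and monotonicities are anchored in the examination literature; the
magnitude is a documented approximation, not a calibrated curve.

**Scale calibration.** `calibrate_scale` images a ruled linear scale held
at the slit-lamp objective (the aerial plane). The dominant line
orientation is found by a Hough transform on Canny edges, intensity is
projected along that orientation, and the pixel pitch is the median
spacing of projection minima — accurate to < 1 % on synthetic rulers,
including rulers rotated by a few degrees. Fewer than three detected lines
is a hard calibration failure; metrology without a calibration raises an
error rather than silently returning pixels.

## Aperture geometry

The illumination column is modelled as a rotating plate with circular
stops of 14/8/3.5/0.3 mm and a crescent, intersected with a "curtain"
rectangle whose width is the slit width. Raster masks live on a mm grid,
origin at the mask centre, row-major, pixel centres at half-integer
offsets; 0.01 mm/px renders circle areas within well under 2 % of π r².
Projection through a lens rescales the mm-per-pixel metadata by 1/m — an
exact operation with no resampling.

The crescent's true dimensions are not published. It is reconstructed
parametrically (outer disc radius 4.0 mm minus a 3.2 mm cutout offset by
1.2 mm), and the "intermediate" plate position places the 3.5 mm stop
2.4 mm above the centre of a 2.5 mm-radius illumination window with the
crescent entering 0.4 mm below the centre-line. With the curtain near
3 mm this yields the characteristic two separated near-semicircles of
unequal area (the patient-visible "structured" stimulus); configurations
that do not produce exactly two components raise a degenerate-mask error.
These dimensions are explicit reconstructions, chosen for the qualitative
two-component geometry, and are fully configurable.

## Slit-beam surface contouring

Forward model (shared by the synthetic renderer and the inverse): with the
illumination arm at angle θ to the observation axis, a surface height h
displaces the imaged slit laterally by Δx = h·tan θ, toward the arm for
elevations and away from it for depressions. All analysis operates in the
viewed (inverted through-the-oculars) frame — the working convention of
slit-lamp practice; an optional `rectify` flips to upright reporting.

The inverse pipeline:

1. **Centreline.** Per-row weighted centroid of pixels above a contrast
   threshold (default 20 % of dynamic range above the 5th percentile).
   Weights saturate at half the band amplitude so that texture *inside*
   the band (vessel shadows, noise) does not bias the centroid while the
   anti-aliased band edges keep sub-pixel information. Accuracy ≤ 0.3 px
   on clean synthetic bands, ≤ 0.5 px mean at 5 % additive noise. A
   uniform frame raises a detection error; multiple separated bands raise
   an ambiguity error listing the candidate columns.
2. **Baseline.** Least-absolute-deviations straight line (statsmodels
   median regression) through centreline rows outside the lesion region;
   at least 20 supporting rows are required. If no exclusion region is
   given it is auto-delineated as the largest contiguous run of residuals
   above 3 MAD from a Theil–Sen first pass (the Theil–Sen intercept is
   recomputed as the median residual so the lesion cannot bias it); this
   stands in for the examiner's manual delineation.
3. **Height.** Deflection (centreline − baseline) is converted px → mm via
   the calibration and lens, signed positive toward the arm, and divided
   by tan θ. Swapping the arm side mirrors the deflection but leaves the
   reconstructed height unchanged — the left/right repeat examination is a
   consistency check, and the implementation averages nothing silently:
   both runs simply reconstruct the same profile.
4. **Lesion metrics.** Depth = −min h; lateral extent = distance between
   the outermost crossings of a threshold at 10 % of peak depth (linear
   interpolation between samples). The 10 % default keeps the extent
   stable against noise and is configurable. With two disjoint pits the
   extent deliberately spans the outermost crossings.

The triangulation ignores refraction of the probing beam inside the eye,
as the classical trigonometric estimate does; for the small angles used
(5–15°) the round-trip error against synthetic ground truth stays within
5 %, and recovered depth is invariant to θ across that range.

## Frame selection

Sharpness is the mean squared response of the discrete Laplacian — a
standard focus measure that strictly decreases under Gaussian blur.
Scoring uses the green channel, where fundus structure contrast is
highest. A frame is a *blink* when its mean intensity is below 30 % of the
sequence-median mean (or below an absolute floor of 0.05, so an all-blink
sequence is still recognised); *saturated* when > 1 % of pixels sit at the
top of the range; *usable* when additionally at or above the 50th
percentile of the remaining sharpness distribution. Selection is greedy
top-k by sharpness with a minimum separation of 12 frames (~0.5 s at the
25 fps reference timebase) so stills span distinct fixation moments. The
blink/saturation thresholds are not anchored in the clinical source; they
were set once against the synthetic generator's regimes and are exposed in
configuration.

## Rigid registration and the flicker test

Flicker pairs are same-lens, same-magnification sessions, so the motion
model is rigid (translation + rotation about the image centre) with
isotropic scale in [0.9, 1.1] only on request; no perspective model is
offered. Estimation:

* difference-of-Gaussians band-pass (σ = 1 and 8 px) isolates vessel-scale
  structure; a flat-topped Tukey taper (α = 0.25) suppresses FFT edge
  effects without destroying energy at large offsets;
* for each candidate rotation (1° grid, then golden-section refinement to
  0.01°) the phase-correlation surface proposes translation peaks; because
  cyclic correlation aliases large shifts, every in-range wrap-around
  interpretation of each peak is scored; the score is the normalised
  cross-correlation over the actual warped overlap (minimum 20 % of the
  frame, rectangle-bound pre-filtered at 18 %);
* the translation is polished to sub-pixel precision by upsampled phase
  correlation restricted to the overlap crop, with the polish clamped to
  3 px (the candidate search is integer, so larger "corrections" are
  spurious);
* acceptance is gated on a trimmed block correlation (worst 20 % of 6×6
  blocks dropped) so locally changed tissue cannot veto — or fake — a
  global alignment.

On synthetic pairs with known transforms, recovery is well within 0.5 px
and 0.2°, forward/backward estimates are mutually inverse to the same
tolerance, and pure translations agree with an exhaustive integer-shift
correlation oracle.

Flicker output alternates the reference and the warped moving image,
masked to their overlap, as a two-phase GIF at a configurable period
(default 500 ms). Photometric defaults for display follow moderate
practice: contrast gain at most 1.20 about a mid-scale pivot and
brightness offset down to −0.10 of full scale (`enhance`); the pivot
choice is this package's convention.

Residual landmark displacements after global alignment are measured by
upsampled phase correlation of Hann-windowed patches (radius 12 px) —
windowing is essential at this patch size, where the cyclic edge
discontinuity otherwise dominates. Landmarks whose patch leaves the
overlap are flagged and excluded from summaries.

## Mosaics and panretinal coverage

Tiles are registered pairwise with the rigid estimator; pair quality is
the NCC of band-passed (vessel-scale) content over the eroded warped
overlap, which rejects pairs whose only agreement is the smooth vignette.
A maximum-quality spanning tree rooted at the most-connected tile chains
the pairwise transforms into a common canvas (tiles are centre-padded so
tile-frame and canvas-frame rigid parameters coincide); a disconnected
overlap graph is a hard error naming the unreachable tiles. Blending is
linear distance-feathering (ramp to full weight 10 px inside each tile's
support). Planar rigid placement is used rather than spherical
reprojection: individual fields are ≤ 45° and clinically produced mosaics
are planar composites. On synthetic tile sets placement error is ≲ 0.01 px
against ground truth — comfortably inside the 1–1.5 px contract — and
invariant to tile order.

Coverage lives on a spherical eye: the retina is the spherical sector
within `retina_halfangle_deg` of the posterior pole and each field is a
cap of half the field diameter around its gaze direction. The default
half-angle of 117° makes the retina ≈ 73 % of the globe and is chosen so
that nine *disjoint* 45° caps cover

9 · (1 − cos 22.5°) / (1 − cos 117°) ≈ 0.471 ≈ 47 %

of the retinal area — the classic panretinal figure. This is a
reconstruction of an unpublished prior model, flagged as such and fully
configurable, not a derivation. `disjoint_nine_field_model` realises the
idealised arrangement (centre + eight tangent caps on the 90° parallel);
the practical 3×3 gaze layout (`grid3x3_layout`, neighbours at a 45° polar
offset) has mutually overlapping diagonal neighbours and covers ≈ 39 %.
Monte-Carlo estimates sample the sector area-uniformly (cos polar uniform)
and report a binomial standard error; they agree with the closed-form cap
area within 3 SE for disjoint configurations, and coverage is monotone in
field count and diameter by construction.

## Synthetic generator

The phantom emulates green-channel fundus appearance: pigmented background
with mild vignetting, a 1.8 mm optic disc with cup, a darker fovea ~2.4
disc-diameters temporal, and a vessel tree grown from the disc margin by
recursive branching with decreasing caliber. Vessel contrast in green is
≥ 2× that in red. Default scale 0.01 mm/px. Additive Gaussian noise
(σ = 0.01) keeps detection thresholds exercised without saturating them.
All generators are deterministic per seed and serialize their ground truth
(offsets, sharp-frame indices, change masks, landmark vectors) so every
downstream test is a self-contained round trip.

What the phantom does *not* model: specular reflexes, media opacity,
photoreceptor texture, pathology beyond pit/bump/vessel-shift/atrophy/
hemorrhage, and photometric nonuniformity beyond vignetting. Passing
round-trip tests therefore demonstrates correctness of the geometry and
estimators under realistic contrast and noise, not clinical performance on
degraded real video.

## Problem sizes and numerical conventions

Tests run phantoms at 256² (512² for mosaics), videos of 50 frames, and
Monte-Carlo coverage at 10⁵ samples — sizes at which every contract
(sub-pixel registration, 5 % contour round trip, 3 SE coverage agreement)
is comfortably resolved. Ties in frame selection break toward the earlier
frame index; transform composition is in homogeneous coordinates about the
image centre; all images are float in [0, 1] internally, 8-bit at the I/O
boundary. Every CLI run writes a manifest (command, config, seeds,
version) sufficient to reproduce its artifacts byte for byte.
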