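# slitfundus

A toolkit for **slit-lamp fundus videography**: quantitative examination of
the retina with nothing more than a standard slit lamp, a hand-held
converging lens (+90/+60/+40 D) and a video camera. It is aimed at
ophthalmologists and vision researchers who want calibrated measurements,
surface contours, longitudinal change detection and panretinal overviews
out of ordinary biomicroscopy video.

## What it computes

**Lens optics and metrology.** A fundus lens of power *P* forms an inverted
aerial image of the retina with transverse magnification *m* (manufacturer
values *m* = 0.75, 1.15, 1.67 for +90, +60, +40 D). Two consequences:

* an illumination aperture of diameter *a* illuminates a retinal field of
  diameter *a / m* — e.g. the 3.5 mm stop lights a 4.7 mm circle through a
  +90 D lens;
* a feature measured as *p* pixels on the monitor, with the pixel scale
  calibrated against a ruled scale held at the slit-lamp objective
  (`calibrate_scale`), has retinal size *p / (px·mm⁻¹) / m*.

Off-catalog powers use the reciprocal-proportionality fit 1/*m* = *P*/*c*.
A first-order vergence factor corrects for uncorrected ametropia.

**Slit-beam surface contouring.** A narrow slit projected at a small angle
θ between the illumination and observation arms is laterally deflected by
surface relief. The deflection Δx (retinal mm) converts to height

&nbsp;&nbsp;&nbsp;&nbsp;*h* = Δx / tan θ,

negative (deflection *away* from the incident arm) over a depression such
as a macular hole, positive over an elevation. The pipeline detects the
band's sub-pixel centreline, fits a robust baseline over undisturbed
retina, and returns a height profile with lesion depth/extent summaries.

**Frame selection.** Laplacian-energy focus scoring of 25 fps video frames
with blink and saturation rejection, picking the sharpest stills separated
in time.

**Flicker registration.** Automatic rigid alignment (translation +
rotation, optional scale) of two visits on vessel-scale structure, flicker
GIF generation, and per-landmark residual displacement vectors.

**Mosaics and coverage.** Rigid stitching of overlapping gaze fields over a
maximum-quality spanning tree with feathered blending, the 3×3 panretinal
gaze scheme, and Monte-Carlo coverage fractions on a spherical eye model
(nine disjoint 45° fields cover ≈ 47 % of a retina modelled as 73 % of the
globe).

**Synthetic fundus generator.** Deterministic phantoms (disc, fovea,
recursive vessel tree, green-dominant contrast), height maps, slit
renderings, tile sets, jittered/blink video and longitudinal change pairs —
every test input carries its ground truth.

## Worked example

```python
from slitfundus import FundusLens, projected_aperture_diameter
from slitfundus.optics import drawback_distance, round_mm

for power in (90, 60, 40):
    lens = FundusLens(power)
    d = projected_aperture_diameter(3.5, lens)
    print(f"+{power}D  m={lens.mag_factor:.2f}  field={round_mm(d):.1f} mm  "
          f"drawback={drawback_distance(lens)[0]:.0f} cm")
```

prints

```
+90D  m=0.75  field=4.7 mm  drawback=3 cm
+60D  m=1.15  field=3.0 mm  drawback=4 cm
+40D  m=1.67  field=2.1 mm  drawback=6 cm
```

i.e. the +90 D lens illuminates the widest fundus field (4.7 mm for the
3.5 mm stop) while needing the least extra working distance; the +60 D
value computes to 3.04 mm (commonly quoted as 3.1 mm, a ≈ 2 % rounding
difference discussed in `docs/methods.md`).

The same numbers are available from the shell:

```sh
slitfundus optics --power 90 --aperture 3.5 --out out/
slitfundus coverage --layout disjoint9 --seed 1 --out out/   # ≈ 0.47
slitfundus simulate --seed 7 --what slit --out out/
slitfundus contour out/slit.png --sidecar out/slit.json --out out/
```

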