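"""Geometric-optics model of hand-held fundus-lens biomicroscopy.

A high-power converging lens (+90/+60/+40 D) held in front of the eye forms
an inverted aerial image of the fundus in the lens's focal plane, which the
slit-lamp microscope then views.  The manufacturers quote, for an emmetropic
schematic eye, a transverse *magnification factor* ``m`` — the ratio of
aerial-image size to true retinal size:

======  =====
power   m
======  =====
+90 D   0.75
+60 D   1.15
+40 D   1.67
======  =====

Two consequences drive everything in this module:

* an aperture of diameter ``a`` in the illumination path is projected onto
  the retina at diameter ``a / m`` (the +90 D lens illuminates the largest
  field), and
* a retinal feature of size ``s`` appears in the aerial image at size
  ``m * s``, so on-screen metrology converts aerial millimetres back to
  retinal millimetres by dividing by ``m``.

For powers off the catalog the reciprocal-proportionality rule
``1/m = P / c`` is used, with ``c`` fitted by least squares to the three
catalog points (residuals < 3 % at each of them).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks
from skimage.feature import canny
from skimage.transform import hough_line, hough_line_peaks

__all__ = [
    "CATALOG_MAG_FACTORS",
    "DRAWBACK_LOOKUP_CM",
    "FundusLens",
    "SchematicEye",
    "ScaleCalibration",
    "UncalibratedError",
    "CalibrationFailure",
    "mag_factor",
    "projected_aperture_diameter",
    "retinal_length",
    "retinal_area",
    "calibrate_scale",
    "drawback_distance",
    "ametropia_factor",
    "round_mm",
]

#: Manufacturer fundus-magnification factors for the standard lens triple.
CATALOG_MAG_FACTORS: dict[float, float] = {90.0: 0.75, 60.0: 1.15, 40.0: 1.67}

#: Extra slit-lamp drawback (vs anterior-segment focus) needed to reach the
#: aerial image, in cm, at the four powers for which a value is quoted.
DRAWBACK_LOOKUP_CM: dict[float, float] = {90.0: 3.0, 60.0: 4.0, 40.0: 6.0, 20.0: 10.0}


class UncalibratedError(ValueError):
    """Metrology was requested without a valid pixel-scale calibration."""


class CalibrationFailure(ValueError):
    """The ruler image did not yield enough ruled lines to calibrate."""


def _fit_reciprocal_constant() -> float:
    """Least-squares ``c`` in ``1/m = P / c`` over the catalog triple.

    Linear regression of 1/m on P through the origin:
    ``1/c = sum(P_i / m_i) / sum(P_i**2)``.
    """
    powers = np.array(sorted(CATALOG_MAG_FACTORS))
    inv_m = 1.0 / np.array([CATALOG_MAG_FACTORS[p] for p in powers])
    return float(np.sum(powers**2) / np.sum(powers * inv_m))


_RECIPROCAL_C: float = _fit_reciprocal_constant()


def round_mm(value_mm: float) -> float:
    """Round a millimetre value to one decimal, half away from zero.

    Matches the style of reported illuminated-field diameters (4.7, 2.1 ...).
    """
    return math.floor(abs(value_mm) * 10.0 + 0.5) / 10.0 * math.copysign(1.0, value_mm)


def mag_factor(power: float) -> tuple[float, bool]:
    """Fundus magnification factor ``m`` for a converging lens of ``power`` D.

    Returns ``(m, catalog)`` where ``catalog`` is True when ``m`` is a printed
    manufacturer value (90/60/40 D) and False when it comes from the fitted
    reciprocal-proportionality rule ``m = c / power``.

    Raises
    ------
    ValueError
        If ``power`` is not strictly positive.
    """
    if not power > 0:
        raise ValueError(f"lens power must be positive, got {power!r}")
    if float(power) in CATALOG_MAG_FACTORS:
        return CATALOG_MAG_FACTORS[float(power)], True
    return _RECIPROCAL_C / float(power), False


@dataclass(frozen=True)
class FundusLens:
    """A hand-held converging fundus lens.

    Parameters
    ----------
    power : float
        Refractive power in diopters, positive.
    mag_factor : float, optional
        Manufacturer fundus-magnification factor ``m`` (aerial-image size =
        ``m`` x retinal size).  Looked up / fitted from ``power`` if omitted.
    catalog : bool
        Whether ``mag_factor`` is a printed manufacturer value.
    """

    power: float
    mag_factor: float = field(default=None)  # type: ignore[assignment]
    catalog: bool = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if not self.power > 0:
            raise ValueError(f"lens power must be positive, got {self.power!r}")
        if self.mag_factor is None:
            m, cat = mag_factor(self.power)
            object.__setattr__(self, "mag_factor", m)
            object.__setattr__(self, "catalog", cat)
        else:
            if not self.mag_factor > 0:
                raise ValueError("mag_factor must be positive")
            if self.catalog is None:
                object.__setattr__(
                    self,
                    "catalog",
                    CATALOG_MAG_FACTORS.get(float(self.power)) == self.mag_factor,
                )


@dataclass(frozen=True)
class SchematicEye:
    """Reduced schematic eye used for ametropia and coverage geometry.

    ``retina_halfangle_deg`` is the angular half-extent of the retina from the
    posterior pole as seen from the globe centre; the default 117 deg makes
    the retina about 73 % of the globe surface.
    """

    axial_length_mm: float = 24.0
    refraction_D: float = 0.0
    globe_radius_mm: float = 12.0
    retina_halfangle_deg: float = 117.0

    def __post_init__(self) -> None:
        if not self.axial_length_mm > 0:
            raise ValueError("axial_length_mm must be positive")
        if not 0 < self.retina_halfangle_deg <= 180:
            raise ValueError("retina_halfangle_deg must be in (0, 180]")


@dataclass(frozen=True)
class ScaleCalibration:
    """Pixel density of the captured image at the aerial-image plane.

    Obtained by imaging a linear scale held in front of the slit-lamp
    objective; ``source`` names the calibration image.
    """

    px_per_mm_aerial: float
    source: str = "unknown"

    def __post_init__(self) -> None:
        if not self.px_per_mm_aerial > 0:
            raise ValueError("px_per_mm_aerial must be positive")


def projected_aperture_diameter(aperture_mm: float, lens: FundusLens) -> float:
    """Diameter on the retina of an illumination aperture of ``aperture_mm``.

    The fundus projection of the aperture is magnified by ``1/m``:
    3.5 mm through a +90 D lens (m = 0.75) illuminates a 4.67 mm (report:
    4.7 mm) circle on the retina.
    """
    if aperture_mm < 0:
        raise ValueError("aperture_mm must be non-negative")
    return aperture_mm / lens.mag_factor


def retinal_length(px: float, cal: ScaleCalibration | None, lens: FundusLens) -> float:
    """Convert a pixel distance measured on the monitor to retinal mm.

    ``px`` pixels at the aerial plane correspond to ``px / px_per_mm_aerial``
    aerial millimetres, and the aerial image is ``m`` times the retina, so the
    retinal length is ``px / px_per_mm_aerial / m``.

    Raises
    ------
    UncalibratedError
        If ``cal`` is None — a raw pixel value is never returned silently.
    """
    if cal is None:
        raise UncalibratedError("no scale calibration: run calibrate_scale first")
    if px < 0:
        raise ValueError("px must be non-negative")
    return px / cal.px_per_mm_aerial / lens.mag_factor


def retinal_area(px_area: float, cal: ScaleCalibration | None, lens: FundusLens) -> float:
    """Convert a pixel area to retinal mm^2 (length conversion squared)."""
    if cal is None:
        raise UncalibratedError("no scale calibration: run calibrate_scale first")
    if px_area < 0:
        raise ValueError("px_area must be non-negative")
    return px_area / cal.px_per_mm_aerial**2 / lens.mag_factor**2


def calibrate_scale(
    image: np.ndarray,
    line_spacing_mm: float,
    *,
    source: str = "ruler",
) -> ScaleCalibration:
    """Calibrate the aerial-plane pixel scale from an image of a ruled scale.

    The image must contain at least three parallel dark ruled lines at a known
    spacing.  The dominant line orientation is found with a Hough transform on
    Canny edges; intensity is then projected along that orientation and the
    median distance between successive projection minima (line centres) gives
    the pixel pitch.

    Raises
    ------
    CalibrationFailure
        If fewer than three ruled lines are detected.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("calibration image must be single-channel")
    if not line_spacing_mm > 0:
        raise ValueError("line_spacing_mm must be positive")
    rng = img.max() - img.min()
    if rng <= 0:
        raise CalibrationFailure("blank calibration image: no ruled lines found")
    norm = (img - img.min()) / rng

    edges = canny(norm, sigma=2.0)
    if not edges.any():
        raise CalibrationFailure("no edges detected in calibration image")
    tested = np.linspace(-np.pi / 2, np.pi / 2, 360, endpoint=False)
    h, angles, dists = hough_line(edges, theta=tested)
    _, peak_angles, _ = hough_line_peaks(h, angles, dists, num_peaks=5)
    if len(peak_angles) == 0:
        raise CalibrationFailure("no straight lines detected in calibration image")
    # Hough theta is the line normal's angle; project intensity along it.
    theta = float(np.median(peak_angles))
    rows, cols = np.mgrid[0 : img.shape[0], 0 : img.shape[1]]
    coord = cols * np.cos(theta) + rows * np.sin(theta)
    nbins = int(np.ptp(coord)) + 1
    idx = np.clip((coord - coord.min()).astype(int), 0, nbins - 1)
    profile = np.bincount(idx.ravel(), weights=norm.ravel(), minlength=nbins)
    counts = np.bincount(idx.ravel(), minlength=nbins)
    valid = counts > 0
    profile[valid] /= counts[valid]

    # Ruled lines are dark: find minima of the projected profile.
    inverted = profile.max() - profile
    prom = 0.25 * (inverted.max() - inverted.min())
    peaks, _ = find_peaks(inverted, prominence=prom, distance=3)
    if len(peaks) < 3:
        raise CalibrationFailure(
            f"only {len(peaks)} ruled lines detected; need at least 3"
        )
    spacing_px = float(np.median(np.diff(peaks)))
    return ScaleCalibration(px_per_mm_aerial=spacing_px / line_spacing_mm, source=source)


def drawback_distance(lens: FundusLens) -> tuple[float, bool]:
    """Extra working distance (cm) needed to focus the aerial image.

    Quoted values exist for +90/+60/+40/+20 D (3/4/6/10 cm).  For other
    powers in [20, 120] D an affine fit in focal length is used,
    ``d ~ 2 f + 9`` mm with ``f = 1000 / power`` mm; fitted values are
    flagged False in the returned ``(cm, quoted)`` tuple.

    Raises
    ------
    ValueError
        If the power is outside [20, 120] D.
    """
    p = float(lens.power)
    if not 20.0 <= p <= 120.0:
        raise ValueError(f"unsupported lens power {p} D: drawback known for 20-120 D")
    if p in DRAWBACK_LOOKUP_CM:
        return DRAWBACK_LOOKUP_CM[p], True
    focal_mm = 1000.0 / p
    return (2.0 * focal_mm + 9.0) / 10.0, False


def ametropia_factor(eye: SchematicEye, lens: FundusLens) -> float:
    """First-order magnification correction for uncorrected refractive error.

    A hyperopic eye (positive spherical equivalent) presents the fundus at
    slightly higher magnification through the same lens, a myopic eye at
    slightly lower; the deviation from unity shrinks with lens power and with
    |refraction|.  Modelled as the vergence ratio

        factor = power / (power - refraction_D)

    which is exactly 1 for emmetropia and first-order antisymmetric in the
    refraction.  Magnitude is an approximation (documented): the examination
    literature fixes only the sign and the monotonicities.
    """
    if abs(eye.refraction_D) > 15:
        raise ValueError("refraction_D outside the +-15 D validity range")
    return lens.power / (lens.power - eye.refraction_D)
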