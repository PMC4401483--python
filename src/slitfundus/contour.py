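"""Surface contouring of the retina from an oblique slit beam.

The optic-section principle: a narrow slit projected at a small angle θ
between the illumination and observation arms is laterally deflected where
the surface height changes.  A deflection Δx (mm, on the retina) converts to
height by

    h = Δx / tan θ

with the sign fixed by the illumination side: in the viewed (inverted) frame
the beam is displaced *away* from the incident arm over a depression (e.g. a
macular hole) and *toward* it over an elevation.  The probing ray's
refraction inside the eye is ignored — the classical trigonometric estimate
does the same; it is a documented approximation.

Pipeline: per-row sub-pixel centreline of the bright band → robust straight
baseline over the undisturbed flanks → deflection → height profile in mm →
lesion depth/extent summaries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

import numpy as np
import statsmodels.api as sm
from scipy import stats
from scipy.signal import find_peaks

from .optics import FundusLens, ScaleCalibration, retinal_length

__all__ = [
    "SlitObservation",
    "HeightProfile",
    "BandDetectionError",
    "BandAmbiguityError",
    "BaselineError",
    "detect_centerline",
    "fit_baseline",
    "height_from_deflection",
    "reconstruct_profile",
    "lesion_metrics",
    "auto_exclusion_mask",
]


class BandDetectionError(ValueError):
    """No slit band with sufficient contrast was found."""


class BandAmbiguityError(ValueError):
    """More than one candidate slit band was found."""

    def __init__(self, candidates_px: list[float]):
        self.candidates_px = candidates_px
        super().__init__(
            f"multiple slit bands detected at columns {candidates_px}; "
            "crop the frame or raise the contrast threshold"
        )


class BaselineError(ValueError):
    """Not enough undisturbed rows to fit the reference line."""


@dataclass(frozen=True)
class SlitObservation:
    """A single frame containing one bright oblique slit band.

    Coordinates are in the viewed (inverted through-the-oculars) frame when
    ``viewed_frame`` is True — the convention all analysis uses.
    """

    image: np.ndarray
    angle_deg: float
    arm_side: Literal["left", "right"]
    cal: ScaleCalibration
    lens: FundusLens
    viewed_frame: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.angle_deg < 90:
            raise ValueError("angle_deg must be in (0, 90)")
        if self.arm_side not in ("left", "right"):
            raise ValueError("arm_side must be 'left' or 'right'")
        if np.asarray(self.image).ndim != 2:
            raise ValueError("slit observation image must be single-channel")

    @property
    def mm_per_px_retina(self) -> float:
        """Retinal mm spanned by one image pixel (aerial scale / m)."""
        return retinal_length(1.0, self.cal, self.lens)


@dataclass(frozen=True)
class HeightProfile:
    """Reconstructed surface height along the slit."""

    position_mm: np.ndarray
    height_mm: np.ndarray
    valid: np.ndarray

    def __post_init__(self) -> None:
        if not (len(self.position_mm) == len(self.height_mm) == len(self.valid)):
            raise ValueError("profile arrays must have equal length")


def detect_centerline(
    obs: SlitObservation, *, contrast_threshold: float = 0.2
) -> np.ndarray:
    """Per-row sub-pixel column of the slit band (intensity-weighted centroid).

    ``contrast_threshold`` is the required band/background contrast as a
    fraction of the image dynamic range.  Rows where the band is absent get
    NaN.  Raises :class:`BandDetectionError` on a uniform/too-dim frame and
    :class:`BandAmbiguityError` (listing candidate columns) when several
    separated bands are present.
    """
    img = np.asarray(obs.image, dtype=float)
    if img.size == 0:
        raise BandDetectionError("empty frame")
    lo, hi = np.percentile(img, [5, 99.9])
    if hi - lo < 1e-6:
        raise BandDetectionError("uniform frame: no slit band")
    thr = lo + contrast_threshold * (hi - lo)

    # Global ambiguity check on the column-wise mean profile.
    colmean = img.mean(axis=0)
    prom = 0.5 * (colmean.max() - colmean.min())
    peaks, _ = find_peaks(colmean, prominence=prom, distance=10)
    if len(peaks) == 0:
        # A single band spanning the frame still yields one dominant max.
        peaks = np.array([int(np.argmax(colmean))])
    if len(peaks) > 1:
        raise BandAmbiguityError([float(p) for p in peaks])

    above = img > thr
    if not above.any():
        raise BandDetectionError("no pixels above the contrast threshold")
    # saturating weights: interior texture of the band (vessel shadows,
    # noise) is flattened out, while the anti-aliased band edges keep their
    # sub-pixel information
    cap = thr + 0.5 * (hi - thr)
    weights = np.clip((img - thr) / (cap - thr), 0.0, 1.0)
    weights[~above] = 0.0
    wsum = weights.sum(axis=1)
    cols = np.arange(img.shape[1])
    with np.errstate(invalid="ignore"):
        centroid = (weights * cols).sum(axis=1) / wsum
    centroid[wsum <= 0] = np.nan
    return centroid


def fit_baseline(
    centerline: np.ndarray,
    exclusion_mask: np.ndarray | None = None,
    *,
    min_support: int = 20,
) -> np.ndarray:
    """Robust straight reference line through the undisturbed slit course.

    Least-absolute-deviations (median regression) fit of column vs row over
    rows outside ``exclusion_mask``; returns the fitted column per row over
    the full length.  Raises :class:`BaselineError` with fewer than
    ``min_support`` supporting rows.
    """
    centerline = np.asarray(centerline, dtype=float)
    rows = np.arange(len(centerline), dtype=float)
    keep = np.isfinite(centerline)
    if exclusion_mask is not None:
        exclusion_mask = np.asarray(exclusion_mask, dtype=bool)
        if exclusion_mask.shape != centerline.shape:
            raise ValueError("exclusion mask must match the centerline length")
        keep &= ~exclusion_mask
    if keep.sum() < min_support:
        raise BaselineError(
            f"only {int(keep.sum())} rows support the baseline; need {min_support}"
        )
    X = sm.add_constant(rows[keep])
    fit = sm.QuantReg(centerline[keep], X).fit(q=0.5)
    return fit.params[0] + fit.params[1] * rows


def auto_exclusion_mask(centerline: np.ndarray, *, k_mad: float = 3.0) -> np.ndarray:
    """Auto-delineate the lesion region for baseline fitting.

    Marks the largest contiguous run of rows whose residual from a first-pass
    straight fit exceeds ``k_mad`` times the median absolute deviation —
    a stand-in for the examiner's manual delineation.
    """
    centerline = np.asarray(centerline, dtype=float)
    rows = np.arange(len(centerline), dtype=float)
    ok = np.isfinite(centerline)
    if ok.sum() < 2:
        return np.zeros_like(ok)
    # Theil-Sen first pass: an ordinary least-squares line would be tilted
    # by the lesion bump itself and leak flank rows into the exclusion mask
    slope, _, _, _ = stats.theilslopes(centerline[ok], rows[ok])
    intercept = float(np.median(centerline[ok] - slope * rows[ok]))
    resid = np.abs(centerline - (intercept + slope * rows))
    mad = np.nanmedian(np.abs(resid - np.nanmedian(resid)))
    out = np.zeros(len(centerline), dtype=bool)
    # on noise-free flanks the MAD collapses to zero: fall back to a small
    # fraction of the peak residual
    scale = k_mad * mad if mad > 0 else 0.01 * np.nanmax(resid)
    if not scale > 0:
        return out
    flagged = resid > scale
    flagged[~ok] = False
    # largest contiguous run
    best_len, best = 0, None
    i = 0
    while i < len(flagged):
        if flagged[i]:
            j = i
            while j < len(flagged) and flagged[j]:
                j += 1
            if j - i > best_len:
                best_len, best = j - i, (i, j)
            i = j
        else:
            i += 1
    if best is not None:
        out[best[0] : best[1]] = True
    return out


def height_from_deflection(
    deflection_mm: float | np.ndarray,
    angle_deg: float,
) -> float | np.ndarray:
    """Convert a signed slit deflection to surface height: h = Δx / tan θ.

    ``deflection_mm`` is signed positive *toward* the illumination arm, so
    positive heights are elevations and negative heights depressions (the
    beam moves away from the incident arm over a hole).
    """
    if not 0 < angle_deg < 90:
        raise ValueError(f"invalid slit geometry: angle {angle_deg} deg not in (0, 90)")
    return deflection_mm / math.tan(math.radians(angle_deg))


def reconstruct_profile(
    obs: SlitObservation,
    exclusion_mask: np.ndarray | None = None,
    *,
    contrast_threshold: float = 0.2,
    auto_exclude: bool = True,
) -> HeightProfile:
    """Full surface reconstruction along the slit.

    centreline − baseline gives the per-row deflection in px; the aerial
    calibration and lens convert it to retinal mm; the tangent rule converts
    it to height.  With no explicit ``exclusion_mask`` the lesion region is
    auto-delineated before the baseline fit.
    """
    centerline = detect_centerline(obs, contrast_threshold=contrast_threshold)
    if exclusion_mask is None and auto_exclude:
        exclusion_mask = auto_exclusion_mask(centerline)
    baseline = fit_baseline(centerline, exclusion_mask)
    deflection_px = centerline - baseline
    # toward-arm is -x for a left arm in the viewed frame
    sgn = -1.0 if obs.arm_side == "left" else 1.0
    mm_per_px = obs.mm_per_px_retina
    deflection_mm = sgn * deflection_px * mm_per_px
    height = height_from_deflection(deflection_mm, obs.angle_deg)
    rows = np.arange(len(centerline), dtype=float)
    valid = np.isfinite(centerline)
    height = np.where(valid, height, 0.0)
    return HeightProfile(
        position_mm=rows * mm_per_px, height_mm=height, valid=valid
    )


def lesion_metrics(
    profile: HeightProfile, *, depth_fraction: float = 0.10
) -> dict:
    """Depth and lateral extent of the dominant depression.

    depth = −min(height); extent = distance between the outermost crossings
    of the threshold ``depth_fraction × depth`` below zero (default 10 %).
    A flat profile returns zeros with ``no_lesion=True``.
    """
    h = np.where(profile.valid, profile.height_mm, 0.0)
    pos = profile.position_mm
    depth = float(-np.min(h)) if len(h) else 0.0
    if depth <= 0:
        return {"depth_mm": 0.0, "extent_mm": 0.0, "no_lesion": True}
    thr = -depth_fraction * depth
    below = h < thr
    if not below.any():
        return {"depth_mm": depth, "extent_mm": 0.0, "no_lesion": True}
    idx = np.flatnonzero(below)
    first, last = idx[0], idx[-1]

    def _cross(i_out: int, i_in: int) -> float:
        if i_out < 0 or i_out >= len(h) or h[i_out] == h[i_in]:
            return float(pos[i_in])
        t = (thr - h[i_out]) / (h[i_in] - h[i_out])
        return float(pos[i_out] + t * (pos[i_in] - pos[i_out]))

    left = _cross(first - 1, first)
    right = _cross(last + 1, last)
    return {"depth_mm": depth, "extent_mm": abs(right - left), "no_lesion": False}
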