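"""Synthetic fundus phantoms with known ground truth.

Generates everything the analysis modules need as test/demo input: a
green-dominant fundus phantom (optic disc, fovea, recursive vessel tree),
signed height maps (pits such as a macular hole, bumps such as a naevus or
detachment), oblique slit-beam renderings over a height map, overlapping
gaze-direction tile sets, jittered/blurred/blink video, and longitudinal
change pairs for flicker testing.

Every generator is deterministic per seed and returns its ground truth
alongside the pixels, so downstream tests are self-contained round trips.
The default scale is 0.01 mm/px at the retinal plane with a 1.8 mm optic
disc — typical adult anatomy.  Vessels are drawn with roughly twice the
contrast in the green channel as in the red, mirroring why green
illumination is preferred for fundus structure.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy import ndimage

from .optics import FundusLens, ScaleCalibration

__all__ = [
    "FundusPhantom",
    "HeightMap",
    "SlitGeometry",
    "generate_phantom",
    "gaussian_pit",
    "gaussian_bump",
    "render_slit",
    "make_tiles",
    "make_video",
    "make_change_pair",
    "calibration_for_phantom",
]

DEFAULT_MM_PER_PX = 0.01
DEFAULT_DISC_DIAMETER_MM = 1.8


@dataclass(frozen=True)
class FundusPhantom:
    """Synthetic fundus image plus its generating ground truth."""

    image: np.ndarray  # HxWx3 float in [0, 1], green-dominant structure
    mm_per_px: float
    disc_center_px: tuple[float, float]  # (row, col)
    disc_diameter_mm: float
    fovea_px: tuple[float, float]
    vessel_points_px: np.ndarray  # (N, 2) float centreline samples (row, col)
    vessel_mask: np.ndarray  # boolean
    seed: int

    @property
    def green(self) -> np.ndarray:
        return self.image[..., 1]


@dataclass(frozen=True)
class HeightMap:
    """Signed surface height (mm) on the phantom grid; zero outside lesions."""

    height_mm: np.ndarray
    lesions: tuple[dict, ...] = ()

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.height_mm)):
            raise ValueError("height map must be finite")


@dataclass(frozen=True)
class SlitGeometry:
    """Slit projection parameters: width, arm angle and arm side."""

    width_mm: float = 0.3
    angle_deg: float = 5.0
    arm_side: Literal["left", "right"] = "left"

    def __post_init__(self) -> None:
        if not self.width_mm > 0:
            raise ValueError("slit width must be positive")
        if not 0 < self.angle_deg < 90:
            raise ValueError("angle_deg must be in (0, 90)")
        if self.arm_side not in ("left", "right"):
            raise ValueError("arm_side must be 'left' or 'right'")


def _draw_disk(canvas: np.ndarray, center: tuple[float, float], radius: float,
               value: float, soft: float = 1.5) -> None:
    rr, cc = np.mgrid[0 : canvas.shape[0], 0 : canvas.shape[1]]
    d = np.hypot(rr - center[0], cc - center[1])
    w = np.clip((radius - d) / soft + 0.5, 0.0, 1.0)
    canvas += value * w


def generate_phantom(
    seed: int,
    *,
    size: tuple[int, int] = (512, 512),
    mm_per_px: float = DEFAULT_MM_PER_PX,
    vessel_density: float = 1.0,
    pigmentation: float = 0.55,
    noise_sigma: float = 0.01,
) -> FundusPhantom:
    """Generate a deterministic fundus phantom.

    The vessel tree grows from the disc margin by recursive branching with
    decreasing caliber.  ``vessel_density`` scales the number of trunks
    (0 disables vessels); ``pigmentation`` sets the green-channel background
    level.  Same seed, same arguments -> bit-identical output.
    """
    if min(size) < 64:
        raise ValueError("phantom must be at least 64x64")
    if vessel_density < 0 or not 0 < pigmentation < 1:
        raise ValueError("degenerate phantom parameters")
    rng = np.random.default_rng(seed)
    h, w = size
    disc_c = (h * 0.5, w * 0.32)
    disc_r_px = DEFAULT_DISC_DIAMETER_MM / 2.0 / mm_per_px
    fovea = (h * 0.5, w * 0.32 + 2.4 * DEFAULT_DISC_DIAMETER_MM / mm_per_px)
    fovea = (float(fovea[0]), float(min(fovea[1], w - 10)))

    # background with mild vignetting
    rr, cc = np.mgrid[0:h, 0:w].astype(float)
    r2 = ((rr - h / 2) / (h / 2)) ** 2 + ((cc - w / 2) / (w / 2)) ** 2
    vignette = 1.0 - 0.25 * r2
    green = pigmentation * vignette
    red = np.clip(pigmentation + 0.22, 0, 1) * vignette
    blue = 0.18 * vignette

    # optic disc: bright, slightly brighter cup
    disc = np.zeros((h, w))
    _draw_disk(disc, disc_c, disc_r_px, 1.0)
    cup = np.zeros((h, w))
    _draw_disk(cup, disc_c, 0.4 * disc_r_px, 1.0)
    green = green + 0.28 * disc + 0.08 * cup
    red = red + 0.18 * disc + 0.05 * cup
    # fovea: darker spot
    fov = np.zeros((h, w))
    _draw_disk(fov, fovea, 0.5 / mm_per_px * 0.35, 1.0, soft=8.0)
    green -= 0.10 * fov
    red -= 0.04 * fov

    # vessel tree
    vessel = np.zeros((h, w))
    points: list[tuple[float, float]] = []
    n_trunks = int(round(6 * vessel_density))

    def grow(pos: np.ndarray, direction: float, width_px: float, depth: int) -> None:
        step = 4.0
        p = pos.copy()
        d = direction
        for _ in range(int(rng.integers(18, 36))):
            d += rng.normal(0.0, 0.09)
            p = p + step * np.array([math.sin(d), math.cos(d)])
            if not (2 <= p[0] < h - 2 and 2 <= p[1] < w - 2):
                return
            _draw_disk(vessel, (p[0], p[1]), width_px, 1.0, soft=1.0)
            points.append((p[0], p[1]))
        if depth < 3 and width_px > 0.8:
            split = rng.uniform(0.25, 0.55)
            grow(p, d + split, width_px * 0.75, depth + 1)
            grow(p, d - split, width_px * 0.75, depth + 1)

    for i in range(n_trunks):
        ang = 2 * math.pi * (i + rng.uniform(-0.2, 0.2)) / max(n_trunks, 1)
        start = np.array(
            [disc_c[0] + disc_r_px * math.sin(ang), disc_c[1] + disc_r_px * math.cos(ang)]
        )
        grow(start, ang, rng.uniform(2.0, 3.2), 0)

    vessel = np.clip(vessel, 0, 1)
    # green contrast ~0.30, red ~0.10: at least 2x
    green = green * (1.0 - 0.55 * vessel)
    red = red * (1.0 - 0.13 * vessel)

    img = np.stack([red, green, blue], axis=-1)
    img += rng.normal(0.0, noise_sigma, img.shape)
    img = np.clip(img, 0.0, 1.0)

    pts = np.array(points, dtype=float) if points else np.empty((0, 2))
    return FundusPhantom(
        image=img,
        mm_per_px=mm_per_px,
        disc_center_px=disc_c,
        disc_diameter_mm=DEFAULT_DISC_DIAMETER_MM,
        fovea_px=fovea,
        vessel_points_px=pts,
        vessel_mask=vessel > 0.5,
        seed=seed,
    )


def _gaussian_lesion(
    shape: tuple[int, int],
    mm_per_px: float,
    center_px: tuple[float, float],
    amplitude_mm: float,
    radius_mm: float,
) -> np.ndarray:
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]].astype(float)
    d_mm = np.hypot(rr - center_px[0], cc - center_px[1]) * mm_per_px
    sigma = radius_mm / 2.0
    hmap = amplitude_mm * np.exp(-0.5 * (d_mm / sigma) ** 2)
    hmap[d_mm > 2.0 * radius_mm] = 0.0  # exact zero outside lesion support
    return hmap


def gaussian_pit(
    shape: tuple[int, int],
    *,
    mm_per_px: float = DEFAULT_MM_PER_PX,
    center_px: tuple[float, float] | None = None,
    depth_mm: float = 0.5,
    radius_mm: float = 0.6,
) -> HeightMap:
    """A macular-hole-like depression: depth > 0 means the pit bottoms at
    ``-depth_mm``."""
    if center_px is None:
        center_px = (shape[0] / 2.0, shape[1] / 2.0)
    hmap = _gaussian_lesion(shape, mm_per_px, center_px, -depth_mm, radius_mm)
    return HeightMap(hmap, ({"type": "pit", "center_px": center_px,
                             "depth_mm": depth_mm, "radius_mm": radius_mm},))


def gaussian_bump(
    shape: tuple[int, int],
    *,
    mm_per_px: float = DEFAULT_MM_PER_PX,
    center_px: tuple[float, float] | None = None,
    height_mm: float = 0.5,
    radius_mm: float = 0.6,
) -> HeightMap:
    """A tumour/detachment-like elevation peaking at ``+height_mm``."""
    if center_px is None:
        center_px = (shape[0] / 2.0, shape[1] / 2.0)
    hmap = _gaussian_lesion(shape, mm_per_px, center_px, height_mm, radius_mm)
    return HeightMap(hmap, ({"type": "bump", "center_px": center_px,
                             "height_mm": height_mm, "radius_mm": radius_mm},))


def calibration_for_phantom(
    phantom_mm_per_px: float, lens: FundusLens, source: str = "synthetic"
) -> ScaleCalibration:
    """Aerial-plane calibration consistent with a phantom's retinal scale.

    Retinal metrology divides aerial mm by ``m``; a phantom pixel spans
    ``mm_per_px`` retinal mm, i.e. ``mm_per_px * m`` aerial mm.
    """
    return ScaleCalibration(
        px_per_mm_aerial=1.0 / (phantom_mm_per_px * lens.mag_factor), source=source
    )


def render_slit(
    phantom: FundusPhantom,
    height_map: HeightMap,
    slit: SlitGeometry,
    *,
    column_px: float | None = None,
    band_gain: float = 0.85,
    background_dim: float = 0.15,
) -> np.ndarray:
    """Render an oblique narrow slit band over the phantom.

    The band runs top-to-bottom near ``column_px``.  At each row the band
    centre is laterally displaced by ``height * tan(angle)`` (mm, converted
    to px): an elevation pushes the band toward the illumination arm, a
    depression away from it.  Outside the band the fundus is dimmed to
    ``background_dim`` of its brightness, mimicking how the non-illuminated
    fundus is practically invisible.

    Returns a single-channel float image in [0, 1].
    """
    g = phantom.green
    h, w = g.shape
    if column_px is None:
        column_px = w / 2.0
    sgn = -1.0 if slit.arm_side == "left" else 1.0
    tan = math.tan(math.radians(slit.angle_deg))
    rows = np.arange(h)
    cols_idx = np.clip(int(round(column_px)), 0, w - 1)
    height_line = height_map.height_mm[:, cols_idx]
    center = column_px + sgn * height_line * tan / phantom.mm_per_px
    half_w = slit.width_mm / 2.0 / phantom.mm_per_px

    cc = np.arange(w)[None, :]
    dist = np.abs(cc - center[:, None])
    band = np.clip(half_w + 0.5 - dist, 0.0, 1.0)  # anti-aliased band profile
    out = g * background_dim + band * (band_gain + (1 - band_gain) * g)
    return np.clip(out, 0.0, 1.0)


@dataclass(frozen=True)
class SyntheticTile:
    """A crop of the phantom with its ground-truth placement."""

    image: np.ndarray
    gaze_label: str
    offset_px: tuple[float, float]  # (row, col) of the crop origin in the phantom
    field_diameter_deg: float
    sidecar: dict = field(default_factory=dict)


def make_tiles(
    phantom: FundusPhantom,
    layout: Literal["pair", "ring6", "grid3x3"] = "grid3x3",
    overlap_deg: float = 2.0,
    *,
    field_diameter_deg: float = 45.0,
    tile_px: int = 160,
) -> list[SyntheticTile]:
    """Cut overlapping tiles with known ground-truth offsets.

    ``overlap_deg`` is converted to pixels via the nominal scale
    ``tile_px / field_diameter_deg``; adjacent tiles overlap by at least that
    amount (0 gives exactly adjacent crops).
    """
    if overlap_deg < 0:
        raise ValueError("overlap_deg must be non-negative")
    h, w = phantom.green.shape
    px_per_deg = tile_px / field_diameter_deg
    step = tile_px - overlap_deg * px_per_deg
    if layout == "pair":
        grid = [("center", 0.0, 0.0), ("temporal", 0.0, 0.7 * tile_px)]
    elif layout == "ring6":
        r = step * 0.62
        grid = [
            (f"ring{i}", r * math.sin(2 * math.pi * i / 6), r * math.cos(2 * math.pi * i / 6))
            for i in range(6)
        ]
    elif layout == "grid3x3":
        names = [
            ["up-nasal", "up", "up-temporal"],
            ["nasal", "center", "temporal"],
            ["down-nasal", "down", "down-temporal"],
        ]
        grid = [
            (names[i][j], (i - 1) * step, (j - 1) * step)
            for i in range(3)
            for j in range(3)
        ]
    else:
        raise ValueError(f"unknown layout {layout!r}")

    tiles = []
    for label, dy, dx in grid:
        r0 = h / 2.0 - tile_px / 2.0 + dy
        c0 = w / 2.0 - tile_px / 2.0 + dx
        ri, ci = int(round(r0)), int(round(c0))
        if ri < 0 or ci < 0 or ri + tile_px > h or ci + tile_px > w:
            raise ValueError(
                f"tile {label!r} at ({ri}, {ci}) exceeds the phantom extent"
            )
        img = phantom.green[ri : ri + tile_px, ci : ci + tile_px].copy()
        tiles.append(
            SyntheticTile(
                image=img,
                gaze_label=label,
                offset_px=(float(ri), float(ci)),
                field_diameter_deg=field_diameter_deg,
                sidecar={
                    "gaze_label": label,
                    "offset_px": [float(ri), float(ci)],
                    "overlap_deg": overlap_deg,
                    "field_diameter_deg": field_diameter_deg,
                    "seed": phantom.seed,
                },
            )
        )
    return tiles


def make_video(
    phantom: FundusPhantom,
    n_frames: int = 50,
    *,
    jitter_px: float = 3.0,
    blur_schedule: np.ndarray | None = None,
    blink_frames: tuple[int, ...] = (),
    seed: int = 0,
) -> tuple[np.ndarray, dict]:
    """Jittered, variably blurred, blink-containing frame sequence.

    ``blur_schedule`` is a per-frame Gaussian sigma (px); frames with sigma 0
    and no blink are the declared-sharp ground truth.  Returns
    ``(frames, truth)`` with frames of shape (n, H, W) in [0, 1].
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    rng = np.random.default_rng(seed)
    g = phantom.green
    if blur_schedule is None:
        blur_schedule = np.zeros(n_frames)
    blur_schedule = np.asarray(blur_schedule, dtype=float)
    if blur_schedule.shape != (n_frames,):
        raise ValueError("blur_schedule must have one sigma per frame")
    frames = np.empty((n_frames, *g.shape))
    shifts = []
    for i in range(n_frames):
        dy, dx = rng.uniform(-jitter_px, jitter_px, size=2) if jitter_px > 0 else (0, 0)
        f = ndimage.shift(g, (dy, dx), order=1, mode="nearest")
        if blur_schedule[i] > 0:
            f = ndimage.gaussian_filter(f, blur_schedule[i])
        if i in blink_frames:
            f = 0.02 * f + rng.normal(0, 0.004, f.shape)
        frames[i] = np.clip(f, 0, 1)
        shifts.append((float(dy), float(dx)))
    sharp = [
        i for i in range(n_frames) if blur_schedule[i] == 0 and i not in blink_frames
    ]
    truth = {
        "sharp_indices": sharp,
        "blink_indices": sorted(blink_frames),
        "blur_sigma": blur_schedule.tolist(),
        "shifts_px": shifts,
        "seed": seed,
    }
    return frames, truth


def make_change_pair(
    phantom: FundusPhantom,
    change_type: Literal["vessel_shift", "atrophy_growth", "hemorrhage"] = "vessel_shift",
    magnitude: float = 2.0,
    *,
    n_landmarks: int = 6,
    seed: int = 0,
) -> dict:
    """Longitudinal before/after pair differing only inside a change mask.

    * ``vessel_shift``: small patches around landmarks arranged on a ring are
      each displaced radially toward the ring centre by ``magnitude`` px — a
      radial tissue contraction.  Landmark ground-truth vectors are recorded.
    * ``atrophy_growth``: a bright atrophic patch grows (brightening inside
      the mask).
    * ``hemorrhage``: a new dark blob.

    Returns a dict with keys ``before, after, change_mask, landmarks_px,
    displacements_px``; pixels outside ``change_mask`` are bit-identical.
    """
    if not magnitude > 0:
        raise ValueError("magnitude must be positive")
    rng = np.random.default_rng(seed)
    g = phantom.green.copy()
    h, w = g.shape
    after = g.copy()
    mask = np.zeros((h, w), dtype=bool)
    center = np.array([h / 2.0, w / 2.0])
    landmarks = []
    displacements = []

    if change_type == "vessel_shift":
        ring_r = min(h, w) * 0.28
        patch_r = int(12 + 5 * magnitude)
        # local texture map: landmarks snap to structured (vessel) points so
        # that patch matching has something to lock onto
        texture = ndimage.uniform_filter(
            (g - ndimage.uniform_filter(g, 9)) ** 2, 9
        )
        for k in range(n_landmarks):
            base = 2 * math.pi * k / n_landmarks + rng.uniform(-0.1, 0.1)
            cands = []
            for da in np.linspace(-0.45, 0.45, 19):
                ang = base + da
                q = center + ring_r * np.array([math.sin(ang), math.cos(ang)])
                qi = (int(round(q[0])), int(round(q[1])))
                if patch_r < qi[0] < h - patch_r and patch_r < qi[1] < w - patch_r:
                    cands.append((texture[qi], q))
            p = max(cands, key=lambda c: c[0])[1]
            direction = (center - p) / np.linalg.norm(center - p)
            shift = magnitude * direction
            r0, c0 = int(p[0]) - patch_r, int(p[1]) - patch_r
            sl = (slice(r0, r0 + 2 * patch_r), slice(c0, c0 + 2 * patch_r))
            patch = ndimage.shift(g[sl], shift, order=1, mode="nearest")
            rr, cc = np.mgrid[0 : 2 * patch_r, 0 : 2 * patch_r]
            inside = np.hypot(rr - patch_r, cc - patch_r) <= patch_r - 1
            region = after[sl]
            region[inside] = patch[inside]
            mask[sl] |= inside
            landmarks.append(tuple(p))
            displacements.append(tuple(shift))
    elif change_type == "atrophy_growth":
        p = center + rng.uniform(-40, 40, 2)
        rr, cc = np.mgrid[0:h, 0:w]
        inside = np.hypot(rr - p[0], cc - p[1]) <= 10 + 4 * magnitude
        after[inside] = np.clip(after[inside] + 0.25, 0, 1)
        mask |= inside
        landmarks.append(tuple(p))
        displacements.append((0.0, 0.0))
    elif change_type == "hemorrhage":
        p = center + rng.uniform(-40, 40, 2)
        rr, cc = np.mgrid[0:h, 0:w]
        inside = np.hypot(rr - p[0], cc - p[1]) <= 5 + 3 * magnitude
        after[inside] = np.clip(after[inside] * 0.35, 0, 1)
        mask |= inside
        landmarks.append(tuple(p))
        displacements.append((0.0, 0.0))
    else:
        raise ValueError(f"unknown change type {change_type!r}")

    return {
        "before": g,
        "after": after,
        "change_mask": mask,
        "landmarks_px": np.array(landmarks),
        "displacements_px": np.array(displacements),
        "seed": seed,
    }
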