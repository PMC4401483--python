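"""Selection of diagnostically usable still frames from fundus video.

Slit-lamp videography records at 25 frames/s while the patient fidgets and
blinks; afterwards the sharpest well-exposed frames are grabbed as stills.
This module scores frames (green channel) with a Laplacian-energy focus
measure, rejects blink and saturated frames, and picks the top-k sharp
frames separated in time so selections span distinct fixation moments.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = ["FrameScore", "SelectionReport", "FRAME_RATE_FPS", "sharpness_score",
           "score_frames", "select_frames"]

#: Reference timebase of the recordings.
FRAME_RATE_FPS = 25.0


@dataclass(frozen=True)
class FrameScore:
    index: int
    sharpness: float
    brightness: float
    blink: bool
    saturated: bool
    usable: bool


@dataclass(frozen=True)
class SelectionReport:
    selected: list[FrameScore]
    scores: list[FrameScore]
    n_blink: int
    n_saturated: int
    n_blurred: int


def sharpness_score(frame: np.ndarray) -> float:
    """Laplacian-energy focus measure: mean squared second derivative.

    Strictly decreases under increasing Gaussian blur of the same
    (non-constant) frame; 0 for a constant frame.
    """
    f = np.asarray(frame, dtype=float)
    if f.size == 0:
        raise ValueError("empty frame")
    if f.ndim != 2:
        raise ValueError("frame must be single-channel (extract green upstream)")
    lap = ndimage.laplace(f)
    return float(np.mean(lap**2))


def score_frames(
    frames: np.ndarray,
    *,
    blink_fraction: float = 0.30,
    blink_floor: float = 0.05,
    saturation_fraction: float = 0.01,
    sharpness_percentile: float = 50.0,
    saturation_level: float = 1.0,
) -> list[FrameScore]:
    """Score every frame of an (n, H, W) sequence.

    A frame is a blink when its mean intensity falls below
    ``blink_fraction`` of the sequence-median mean or below the absolute
    ``blink_floor`` (so an all-blink sequence is still recognised);
    saturated when more than
    ``saturation_fraction`` of its pixels sit at ``saturation_level``.
    Usable frames additionally reach the ``sharpness_percentile`` of the
    non-blink, non-saturated sharpness distribution.
    """
    frames = np.asarray(frames, dtype=float)
    if frames.ndim != 3 or frames.shape[0] == 0:
        raise ValueError("frames must be a non-empty (n, H, W) stack")
    means = frames.mean(axis=(1, 2))
    med = float(np.median(means))
    blink = means < max(blink_fraction * med, blink_floor)
    sat = (frames >= saturation_level).mean(axis=(1, 2)) > saturation_fraction
    sharp = np.array([sharpness_score(f) for f in frames])
    ok = ~blink & ~sat
    thr = float(np.percentile(sharp[ok], sharpness_percentile)) if ok.any() else np.inf
    return [
        FrameScore(
            index=i,
            sharpness=float(sharp[i]),
            brightness=float(means[i]),
            blink=bool(blink[i]),
            saturated=bool(sat[i]),
            usable=bool(ok[i] and sharp[i] >= thr),
        )
        for i in range(len(frames))
    ]


def select_frames(
    frames: np.ndarray,
    k: int,
    min_separation_frames: int = 12,
    **score_kwargs,
) -> SelectionReport:
    """Pick up to ``k`` usable frames, greedily by sharpness, no two within
    ``min_separation_frames`` (default ~0.5 s at 25 fps).

    Blink and saturated frames are excluded before ranking.  If nothing is
    usable the selection is empty and the report carries diagnostic counts.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    scores = score_frames(frames, **score_kwargs)
    usable = sorted(
        (s for s in scores if s.usable), key=lambda s: (-s.sharpness, s.index)
    )
    chosen: list[FrameScore] = []
    for s in usable:
        if len(chosen) >= k:
            break
        if all(abs(s.index - c.index) >= min_separation_frames for c in chosen):
            chosen.append(s)
    return SelectionReport(
        selected=chosen,
        scores=scores,
        n_blink=sum(s.blink for s in scores),
        n_saturated=sum(s.saturated for s in scores),
        n_blurred=sum((not s.usable) and not s.blink and not s.saturated for s in scores),
    )
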