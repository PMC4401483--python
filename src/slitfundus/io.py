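"""Configuration, manifests, image/sidecar plumbing and display enhancement.

Every CLI run validates its configuration up front and writes a manifest
(config + package version + seeds) next to its artifacts, so any artifact is
reproducible from the manifest alone.  Images travel as PNG/TIFF with JSON
sidecars for metadata; fundus images stay in the viewed (inverted) frame by
default, matching clinical slit-lamp use, with an explicit rectify step for
upright reporting.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["RunConfig", "ConfigError", "enhance", "rectify", "load_image",
           "save_image", "save_sidecar", "load_sidecar", "write_manifest"]

#: Display-enhancement bounds: up to +20 % contrast, up to −10 % brightness.
MAX_CONTRAST_GAIN = 1.20
MIN_BRIGHTNESS_OFFSET = -0.10
CONTRAST_PIVOT = 0.5


class ConfigError(ValueError):
    """The run configuration failed schema validation."""


@dataclass
class RunConfig:
    """Validated per-run configuration shared by the CLI subcommands."""

    lens_power: float = 90.0
    aperture_mm: float = 3.5
    angle_deg: float = 5.0
    arm_side: str = "left"
    channel: str = "green"
    contrast_gain: float = MAX_CONTRAST_GAIN
    brightness_offset: float = MIN_BRIGHTNESS_OFFSET
    seed: int = 0
    rectify: bool = False
    out_dir: str = "slitfundus_out"
    px_per_mm_aerial: float | None = None
    extra: dict = field(default_factory=dict)

    def validate(self) -> "RunConfig":
        if not self.lens_power > 0:
            raise ConfigError("lens_power must be positive")
        if self.aperture_mm < 0:
            raise ConfigError("aperture_mm must be non-negative")
        if not 0 < self.angle_deg < 90:
            raise ConfigError("angle_deg must be in (0, 90)")
        if self.arm_side not in ("left", "right"):
            raise ConfigError("arm_side must be 'left' or 'right'")
        if self.channel not in ("green", "red", "blue"):
            raise ConfigError("channel must be one of green/red/blue")
        if not 0 < self.contrast_gain <= MAX_CONTRAST_GAIN:
            raise ConfigError(f"contrast_gain must be in (0, {MAX_CONTRAST_GAIN}]")
        if not MIN_BRIGHTNESS_OFFSET <= self.brightness_offset <= 0.5:
            raise ConfigError(
                f"brightness_offset must be >= {MIN_BRIGHTNESS_OFFSET}"
            )
        return self

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        data = json.loads(Path(path).read_text())
        known = {k: v for k, v in data.items() if k in cls.__dataclass_fields__}
        unknown = {k: v for k, v in data.items() if k not in cls.__dataclass_fields__}
        cfg = cls(**known)
        cfg.extra.update(unknown)
        return cfg.validate()


def enhance(
    image: np.ndarray,
    contrast_gain: float = MAX_CONTRAST_GAIN,
    brightness_offset: float = MIN_BRIGHTNESS_OFFSET,
) -> np.ndarray:
    """Affine display enhancement about a mid-scale pivot, clipped to [0, 1].

    ``out = (img - 0.5) * gain + 0.5 + offset``.  The defaults are the
    moderate settings used for fundus video stills: contrast up by at most
    20 %, brightness down by 10 % of full scale.
    """
    if not 0 < contrast_gain <= MAX_CONTRAST_GAIN:
        raise ValueError(f"contrast_gain above the {MAX_CONTRAST_GAIN} bound")
    if brightness_offset < MIN_BRIGHTNESS_OFFSET:
        raise ValueError(f"brightness_offset below the {MIN_BRIGHTNESS_OFFSET} bound")
    img = np.asarray(image, dtype=float)
    out = (img - CONTRAST_PIVOT) * contrast_gain + CONTRAST_PIVOT + brightness_offset
    return np.clip(out, 0.0, 1.0)


def rectify(image: np.ndarray) -> np.ndarray:
    """Flip the viewed (inverted) frame to upright-fundus orientation."""
    return np.asarray(image)[::-1, ::-1].copy()


def load_image(path: str | Path, *, as_float: bool = True) -> np.ndarray:
    import imageio.v3 as iio

    img = iio.imread(path)
    if as_float and np.issubdtype(img.dtype, np.integer):
        img = img.astype(float) / np.iinfo(img.dtype).max
    return img


def save_image(path: str | Path, image: np.ndarray) -> None:
    import imageio.v3 as iio

    img = np.asarray(image)
    if np.issubdtype(img.dtype, np.floating):
        img = np.clip(img * 255.0, 0, 255).astype(np.uint8)
    iio.imwrite(Path(path), img)


def save_sidecar(path: str | Path, data: dict) -> None:
    Path(path).write_text(json.dumps(data, indent=2, default=_jsonable) + "\n")


def load_sidecar(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating, np.bool_)):
        return obj.item()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def write_manifest(out_dir: str | Path, config: RunConfig, *, command: str) -> Path:
    from . import __version__

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "command": command,
        "config": asdict(config),
        "version": __version__,
        "seed": config.seed,
    }
    p = out / "manifest.json"
    save_sidecar(p, manifest)
    return p
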