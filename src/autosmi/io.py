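"""File formats: multi-page TIFF stacks, CSV tables, key=value config files."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import tifffile


@dataclass
class ImageStack:
    """A fluorescence or bright-field movie plus its physical calibration.

    frames : (T, H, W) array, arbitrary camera units.
    pixel_size : um per pixel.
    frame_interval : seconds between frames (33 ms by default upstream).
    channel : free-form tag ("green", "red", "sric", ...).
    """

    frames: np.ndarray
    pixel_size: float = 0.1
    frame_interval: float = 0.033
    channel: str = "green"

    def __post_init__(self):
        self.frames = np.asarray(self.frames)
        if self.frames.ndim == 2:
            self.frames = self.frames[None]
        if self.frames.ndim != 3:
            raise ValueError(f"frames must be (T, H, W), got {self.frames.shape}")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self):
        return self.frames.shape

    def save(self, path) -> None:
        tifffile.imwrite(path, self.frames.astype(np.float32),
                         photometric="minisblack",
                         metadata={"pixel_size_um": self.pixel_size,
                                   "frame_interval_s": self.frame_interval,
                                   "channel": self.channel})

    @classmethod
    def load(cls, path, pixel_size: float = 0.1, frame_interval: float = 0.033,
             channel: str = "green") -> "ImageStack":
        frames = tifffile.imread(path)
        return cls(frames=np.asarray(frames, dtype=np.float64),
                   pixel_size=pixel_size, frame_interval=frame_interval,
                   channel=channel)


def read_config(path) -> dict:
    """Parse a plain-text ``key = value`` config file.

    Lines starting with ``#`` and blank lines are ignored; values are
    auto-coerced to int/float/bool where possible.
    """
    out: dict = {}
    with open(path) as fh:
        for raw in fh:
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"malformed config line: {raw!r}")
            key, value = (part.strip() for part in line.split("=", 1))
            out[key] = _coerce(value)
    return out


def write_config(cfg: dict, path) -> None:
    with open(path, "w") as fh:
        for key, value in cfg.items():
            fh.write(f"{key} = {value}\n")


def _coerce(value: str):
    low = value.lower()
    if low in ("true", "false"):
        return low == "true"
    for cast in (int, float):
        try:
            return cast(value)
        except ValueError:
            pass
    return value
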