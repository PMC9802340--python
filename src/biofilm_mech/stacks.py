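"""Time-lapse image stacks with physical calibration.

An :class:`ImageStack` is the raw input to both analysis arms: bright-field
colony imagery feeds the boundary tracker, fluorescent-bead imagery feeds the
PIV stage.  Frames are stored as a single ``(T, H, W)`` array together with the
pixel size (µm/px) and the frame interval (min), which every downstream unit
conversion goes through.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import tifffile

__all__ = ["ImageStack"]


@dataclass
class ImageStack:
    """Ordered grayscale frames with acquisition metadata.

    Parameters
    ----------
    frames
        Array of shape ``(T, H, W)``; 16-bit unsigned integers for rendered
        imagery, though float frames are accepted for intermediate data.
    pixel_size
        Physical size of one pixel, µm/px.
    frame_interval
        Time between consecutive frames, minutes.
    channel
        Free-text channel label, e.g. ``"brightfield"`` or ``"beads"``.
    """

    frames: np.ndarray
    pixel_size: float
    frame_interval: float
    channel: str = ""

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError(f"frames must be (T, H, W); got shape {self.frames.shape}")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        """Frame shape ``(H, W)`` in pixels."""
        return self.frames.shape[1:]

    @property
    def times(self) -> np.ndarray:
        """Frame timestamps in minutes, starting at 0."""
        return np.arange(self.n_frames) * self.frame_interval

    def __len__(self) -> int:
        return self.n_frames

    def __getitem__(self, i: int) -> np.ndarray:
        return self.frames[i]

    # ------------------------------------------------------------------ I/O
    def save(self, path) -> None:
        """Write a multi-page TIFF with calibration in the image description."""
        meta = {
            "pixel_size_um": float(self.pixel_size),
            "frame_interval_min": float(self.frame_interval),
            "channel": self.channel,
        }
        tifffile.imwrite(path, self.frames, photometric="minisblack",
                         description=json.dumps(meta, sort_keys=True))

    @classmethod
    def load(cls, path, pixel_size: float | None = None,
             frame_interval: float | None = None, channel: str = "") -> "ImageStack":
        """Read a multi-page TIFF.

        Calibration is taken from the JSON image description written by
        :meth:`save`; explicit arguments override it (required for TIFFs from
        other sources, which carry no calibration).
        """
        with tifffile.TiffFile(path) as tif:
            frames = tif.asarray()
            desc = tif.pages[0].description or ""
        if frames.ndim == 2:
            frames = frames[None]
        meta = {}
        try:
            meta = json.loads(desc)
        except (json.JSONDecodeError, TypeError):
            pass
        ps = pixel_size if pixel_size is not None else meta.get("pixel_size_um")
        fi = frame_interval if frame_interval is not None else meta.get("frame_interval_min")
        if ps is None or fi is None:
            raise ValueError(
                f"{path}: pixel_size and frame_interval not found in TIFF metadata; "
                "pass them explicitly"
            )
        return cls(frames, float(ps), float(fi), channel or meta.get("channel", ""))
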