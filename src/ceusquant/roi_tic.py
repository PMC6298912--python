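"""ROI-based time-intensity curve extraction from cine loops.

A cine loop is a 3-D stack (frame x row x column) of linearised contrast
intensities acquired at a fixed frame interval.  The ovary is outlined
once as a boolean mask drawn along its perimeter; the TIC is the
arithmetic mean of in-mask pixels per frame.  The mask is fixed for the
whole loop: acquisitions are made with the probe clamped on a rail, so no
motion correction is applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .tic_model import TimeIntensityCurve

__all__ = ["CineLoop", "RoiMask", "extract_tic"]

DEFAULT_FRAME_INTERVAL = 1.0 / 36.0  # s, 36 frames/s acquisition


@dataclass(frozen=True)
class CineLoop:
    """An intensity cine loop.

    ``frames``: (n_frames, rows, cols) array of finite, non-negative
    intensities (a.u.); ``frame_interval``: seconds between frames;
    ``pixel_size``: mm per pixel (isotropic).
    """

    frames: np.ndarray
    frame_interval: float = DEFAULT_FRAME_INTERVAL
    pixel_size: float = 0.05
    meta: Mapping = field(default_factory=dict)

    def __post_init__(self) -> None:
        f = np.asarray(self.frames, dtype=float)
        if f.ndim != 3:
            raise ValueError("frames must be a 3-D (frame, row, col) stack")
        if f.shape[0] < 8:
            raise ValueError("a cine loop needs at least 8 frames")
        if not np.all(np.isfinite(f)) or np.any(f < 0):
            raise ValueError("frame intensities must be finite and non-negative")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        object.__setattr__(self, "frames", f)

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]

    @property
    def times(self) -> np.ndarray:
        """Frame times in seconds, frame 0 at acquisition start."""
        return np.arange(self.n_frames) * self.frame_interval


@dataclass(frozen=True)
class RoiMask:
    """A boolean region-of-interest mask in frame geometry."""

    mask: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.mask)
        if m.ndim != 2:
            raise ValueError("mask must be 2-D")
        m = m.astype(bool)
        if not m.any():
            raise ValueError("mask must contain at least one pixel")
        object.__setattr__(self, "mask", m)

    @property
    def n_pixels(self) -> int:
        return int(self.mask.sum())


def extract_tic(cine: CineLoop, roi: RoiMask) -> TimeIntensityCurve:
    """Mean in-ROI intensity per frame as a time-intensity curve.

    Raises ``ValueError`` on a spatial dimension mismatch.  The returned
    curve carries the ROI pixel count and frame interval in its metadata.
    """
    if roi.mask.shape != cine.frame_shape:
        raise ValueError(
            f"mask shape {roi.mask.shape} does not match frames {cine.frame_shape}"
        )
    means = cine.frames[:, roi.mask].mean(axis=1)
    meta = dict(cine.meta)
    meta.update(roi_pixels=roi.n_pixels, frame_interval=cine.frame_interval)
    return TimeIntensityCurve(times=cine.times, intensities=means, meta=meta)
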