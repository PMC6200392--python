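"""Two-channel kymograph container.

A kymograph is a space-time image: one row per acquired frame, one column per
pixel along the line joining a pair of crosslinked microtubules. Channel 0 is
the microtubule (rhodamine) channel, channel 1 the motor/crosslinker (GFP)
channel. Physical calibration (pixel size in nm, frame interval in s) is part
of the object; all downstream measurements are reported in nm and seconds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

MT_CHANNEL = 0
GFP_CHANNEL = 1


@dataclass
class Kymograph:
    """Calibrated two-channel space-time image.

    Parameters
    ----------
    pixels:
        Array of shape ``(2, n_frames, n_pixels)``; intensities must be
        non-negative. Channel 0 = microtubule channel, channel 1 = GFP.
    pixel_size:
        nm per pixel (> 0).
    frame_interval:
        seconds per kymograph line (> 0).
    origin:
        Physical position (nm) of the left edge of pixel 0. Lets rendered
        kymographs share a coordinate axis with their ground truth.
    meta:
        Free-form metadata (event id, condition label, ...).
    """

    pixels: np.ndarray
    pixel_size: float
    frame_interval: float
    origin: float = 0.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[0] != 2:
            raise ValueError(
                f"expected pixels of shape (2, n_frames, n_pixels), got {self.pixels.shape}"
            )
        if np.any(self.pixels < 0):
            raise ValueError("kymograph intensities must be non-negative")
        if not (self.pixel_size > 0 and self.frame_interval > 0):
            raise ValueError("pixel_size and frame_interval must be positive")

    @property
    def n_frames(self) -> int:
        return self.pixels.shape[1]

    @property
    def n_pixels(self) -> int:
        return self.pixels.shape[2]

    @property
    def mt(self) -> np.ndarray:
        """Microtubule (rhodamine) channel, shape (n_frames, n_pixels)."""
        return self.pixels[MT_CHANNEL]

    @property
    def gfp(self) -> np.ndarray:
        """GFP channel, shape (n_frames, n_pixels)."""
        return self.pixels[GFP_CHANNEL]

    def x_nm(self) -> np.ndarray:
        """Physical positions (nm) of pixel centres."""
        return self.origin + (np.arange(self.n_pixels) + 0.5) * self.pixel_size

    def t_s(self) -> np.ndarray:
        """Acquisition times (s) of each line."""
        return np.arange(self.n_frames) * self.frame_interval
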