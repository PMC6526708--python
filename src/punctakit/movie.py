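"""Calibrated single-channel time-lapse container.

A :class:`Movie` is a T×H×W stack of nonnegative intensities plus the two
calibration constants every downstream quantity depends on: the lateral pixel
size (µm/px, converts areas to µm² and densities to dots/µm²) and the frame
interval (s, converts frame lags to seconds).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class Movie:
    """Single-channel, single-plane time-lapse stack.

    Parameters
    ----------
    frames : ndarray, shape (T, H, W)
        Nonnegative intensities; float or unsigned integer.
    pixel_size_um : float
        Lateral pixel size in µm/px (> 0).
    frame_interval_s : float
        Time between consecutive frames in seconds (> 0).
    channel : str
        Free-form channel label (e.g. ``"DYN2"``, ``"A"``).
    """

    frames: np.ndarray
    pixel_size_um: float
    frame_interval_s: float
    channel: str = "unnamed"

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError(f"frames must be T×H×W, got shape {self.frames.shape}")
        t, h, w = self.frames.shape
        if t < 1 or h < 8 or w < 8:
            raise ValueError(f"need T ≥ 1 and H,W ≥ 8, got {self.frames.shape}")
        if not (self.pixel_size_um > 0):
            raise ValueError(f"pixel_size_um must be > 0, got {self.pixel_size_um}")
        if not (self.frame_interval_s > 0):
            raise ValueError(f"frame_interval_s must be > 0, got {self.frame_interval_s}")
        if not np.all(np.isfinite(self.frames)):
            raise ValueError("frames contain non-finite values")
        if np.any(self.frames < 0):
            raise ValueError("frames contain negative intensities")

    @property
    def n_frames(self) -> int:
        return int(self.frames.shape[0])

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(self.frames.shape)  # type: ignore[return-value]

    @property
    def duration_s(self) -> float:
        return self.n_frames * self.frame_interval_s

    @property
    def times_s(self) -> np.ndarray:
        """Frame acquisition times, ``frame_index * frame_interval_s``."""
        return np.arange(self.n_frames) * self.frame_interval_s

    @property
    def field_area_um2(self) -> float:
        t, h, w = self.frames.shape
        return h * w * self.pixel_size_um**2

    def same_calibration(self, other: "Movie", rtol: float = 1e-9) -> bool:
        return (
            self.frames.shape == other.frames.shape
            and np.isclose(self.pixel_size_um, other.pixel_size_um, rtol=rtol)
            and np.isclose(self.frame_interval_s, other.frame_interval_s, rtol=rtol)
        )
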