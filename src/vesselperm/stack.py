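"""Calibrated time-lapse image stacks.

The package-wide pixel convention is 0-based ``(row, col) = (y, x)`` indexing,
time in seconds measured from the first frame. Stacks are stored as numpy
arrays ordered ``(time, channel, y, x)`` or ``(time, channel, z, y, x)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["FrameStack", "DriftTrace"]


@dataclass
class FrameStack:
    """A calibrated multi-channel time series image.

    Parameters
    ----------
    pixels : ndarray
        Array of shape ``(T, C, Y, X)`` or ``(T, C, Z, Y, X)``, arbitrary
        intensity units.
    pixel_size : float
        Lateral calibration in µm/px (isotropic in x and y).
    frame_interval : float
        Time between consecutive frames in seconds.
    z_step : float, optional
        Axial spacing in µm; only meaningful for 5-D stacks.
    channel_names : list of str, optional
        One label per channel; defaults to ``ch0, ch1, ...``.
    origin_time : float
        Acquisition time of frame 0 in seconds.
    """

    pixels: np.ndarray
    pixel_size: float
    frame_interval: float
    z_step: float | None = None
    channel_names: list[str] = field(default_factory=list)
    origin_time: float = 0.0

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim not in (4, 5):
            raise ValueError(
                f"pixels must be (T, C, Y, X) or (T, C, Z, Y, X); got shape {self.pixels.shape}"
            )
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be > 0")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")
        if self.n_frames < 1 or self.n_channels < 1:
            raise ValueError("stack needs at least one frame and one channel")
        if not self.channel_names:
            self.channel_names = [f"ch{i}" for i in range(self.n_channels)]
        if len(self.channel_names) != self.n_channels:
            raise ValueError("channel_names length must match channel count")

    @property
    def n_frames(self) -> int:
        return self.pixels.shape[0]

    @property
    def n_channels(self) -> int:
        return self.pixels.shape[1]

    @property
    def has_z(self) -> bool:
        return self.pixels.ndim == 5

    @property
    def frame_shape(self) -> tuple[int, int]:
        """(height, width) in pixels."""
        return self.pixels.shape[-2], self.pixels.shape[-1]

    @property
    def times(self) -> np.ndarray:
        """Time coordinate of every frame in seconds."""
        return self.origin_time + np.arange(self.n_frames) * self.frame_interval

    def with_pixels(self, pixels: np.ndarray) -> "FrameStack":
        """Copy of this stack with the pixel array replaced, calibration kept."""
        return replace(self, pixels=pixels, channel_names=list(self.channel_names))

    def channel_index(self, channel: int | str) -> int:
        if isinstance(channel, str):
            try:
                return self.channel_names.index(channel)
            except ValueError:
                raise KeyError(f"unknown channel {channel!r}") from None
        if not 0 <= channel < self.n_channels:
            raise IndexError(f"channel {channel} out of range")
        return int(channel)


@dataclass
class DriftTrace:
    """Per-frame rigid offsets (dy, dx) in px relative to a reference frame."""

    dy: np.ndarray
    dx: np.ndarray
    dz: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.dy = np.asarray(self.dy, dtype=float)
        self.dx = np.asarray(self.dx, dtype=float)
        if self.dz is not None:
            self.dz = np.asarray(self.dz, dtype=float)
        if len(self.dy) != len(self.dx):
            raise ValueError("dy and dx must have equal length")
        if len(self.dy) == 0:
            raise ValueError("empty drift trace")

    def __len__(self) -> int:
        return len(self.dy)

    @property
    def xy_magnitude(self) -> np.ndarray:
        """Per-frame Euclidean XY drift magnitude in px."""
        return np.hypot(self.dy, self.dx)

    def to_dataframe(self):
        import pandas as pd

        data = {"frame": np.arange(len(self)), "dy_px": self.dy, "dx_px": self.dx}
        if self.dz is not None:
            data["dz_px"] = self.dz
        return pd.DataFrame(data)
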