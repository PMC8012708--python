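"""Time-stamped 8-bit greyscale frame stacks with ROI and optical scale.

The camera-facing container shared by the bubble-sizing and mixing-time
stages.  Conventions: row-major arrays, origin top-left, ROI given as a
half-open rectangle ``(row_min, row_max, col_min, col_max)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["FrameSequence"]


@dataclass
class FrameSequence:
    """Stack of 8-bit greyscale frames plus acquisition metadata.

    Attributes
    ----------
    frames
        ``(n_frames, rows, cols)`` uint8 array.
    timestamps
        Frame times in seconds, strictly increasing.
    fps
        Nominal frame rate (frames s⁻¹).
    pixel_scale_mm
        Physical size of one pixel in millimetres (isotropic optics assumed).
    roi
        Half-open rectangle ``(row_min, row_max, col_min, col_max)``; defaults
        to the full frame.
    ground_truth
        Optional generator-attached record (synthetic sequences only).
    """

    frames: np.ndarray
    timestamps: np.ndarray
    fps: float
    pixel_scale_mm: float
    roi: tuple[int, int, int, int] | None = None
    ground_truth: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (n, rows, cols) stack")
        if self.frames.dtype != np.uint8:
            raise ValueError("frames must be 8-bit greyscale (uint8)")
        if len(self.timestamps) != len(self.frames):
            raise ValueError("one timestamp per frame required")
        if len(self.timestamps) > 1 and not np.all(np.diff(self.timestamps) > 0):
            raise ValueError("timestamps must be strictly increasing")
        if self.fps <= 0:
            raise ValueError("fps must be > 0")
        if self.pixel_scale_mm <= 0:
            raise ValueError("pixel_scale_mm must be > 0")
        if self.roi is None:
            self.roi = (0, self.frames.shape[1], 0, self.frames.shape[2])
        r0, r1, c0, c1 = self.roi
        rows, cols = self.frames.shape[1:]
        if not (0 <= r0 < r1 <= rows and 0 <= c0 < c1 <= cols):
            raise ValueError(f"roi {self.roi} outside frame bounds {rows}x{cols}")

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def shape(self) -> tuple[int, int]:
        """(rows, cols) of a single frame."""
        return self.frames.shape[1:]

    def roi_view(self, index: int) -> np.ndarray:
        """ROI crop of frame ``index`` (a view, not a copy)."""
        r0, r1, c0, c1 = self.roi
        return self.frames[index, r0:r1, c0:c1]
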