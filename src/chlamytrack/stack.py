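"""Calibrated time-lapse image stacks.

An :class:`ImageStack` couples the raw frame array with the two pieces of
calibration metadata the whole pipeline depends on: the pixel size (µm/px,
measured with a micrometer ruler slide) and the frame interval (s), obtained
by dividing the video duration by the number of image slices.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class ImageStack:
    """A grayscale time-lapse: frames indexed ``(t, y, x)`` plus calibration.

    Parameters
    ----------
    frames
        3-D intensity array, time first, y downward, x rightward.
    pixel_size_um
        Physical size of one pixel in micrometers.
    frame_interval_s
        Time between consecutive frames in seconds.
    """

    frames: np.ndarray
    pixel_size_um: float
    frame_interval_s: float

    def __post_init__(self) -> None:
        frames = np.asarray(self.frames)
        if frames.ndim != 3:
            raise ValueError(f"frames must be 3-D (t, y, x); got shape {frames.shape}")
        if frames.size == 0:
            raise ValueError("empty image stack")
        if not self.pixel_size_um > 0:
            raise ValueError(f"pixel_size_um must be positive; got {self.pixel_size_um}")
        if not self.frame_interval_s > 0:
            raise ValueError(f"frame_interval_s must be positive; got {self.frame_interval_s}")
        object.__setattr__(self, "frames", frames)

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def height_px(self) -> int:
        return self.frames.shape[1]

    @property
    def width_px(self) -> int:
        return self.frames.shape[2]

    @property
    def duration_s(self) -> float:
        """Total video duration, ``n_frames * frame_interval_s``."""
        return self.n_frames * self.frame_interval_s
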