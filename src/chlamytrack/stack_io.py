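"""Reading and writing calibrated time-lapse stacks.

Multi-page grayscale TIFF is the canonical interchange format (one page per
frame, 16-bit). Calibration is never guessed from file metadata: the caller
supplies the pixel size and either the frame interval or the video duration
(interval = duration / n_frames). AVI input is best-effort via imageio when
a decoder is available.
"""

from __future__ import annotations

import os
from typing import Optional

import numpy as np
import tifffile

from .errors import ValidationError
from .stack import ImageStack

__all__ = ["read_stack", "write_stack"]


def write_stack(stack: ImageStack, path: str | os.PathLike) -> None:
    """Write a stack as a multi-page 16-bit grayscale TIFF."""
    frames = stack.frames
    if frames.dtype != np.uint16:
        frames = np.clip(np.rint(frames.astype(np.float64)), 0, 65535).astype(np.uint16)
    tifffile.imwrite(path, frames, photometric="minisblack")


def _calibration(
    n_frames: int,
    pixel_size_um: float,
    frame_interval_s: Optional[float],
    duration_s: Optional[float],
) -> float:
    if frame_interval_s is not None and duration_s is not None:
        if abs(frame_interval_s * n_frames - duration_s) > 1e-6 * max(duration_s, 1.0):
            raise ValidationError(
                "frame_interval_s and duration_s are inconsistent: "
                f"{frame_interval_s} * {n_frames} != {duration_s}"
            )
        return frame_interval_s
    if frame_interval_s is not None:
        return frame_interval_s
    if duration_s is not None:
        return duration_s / n_frames
    raise ValidationError("provide frame_interval_s or duration_s")


def read_stack(
    path: str | os.PathLike,
    pixel_size_um: float,
    frame_interval_s: Optional[float] = None,
    duration_s: Optional[float] = None,
) -> ImageStack:
    """Read a multi-page grayscale TIFF (or, best-effort, an AVI) stack.

    Frames are ordered by page index. The frame interval is taken from
    ``frame_interval_s`` or computed as ``duration_s / n_frames``.
    Non-grayscale pages raise an unsupported-format error naming the page.
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    if path.lower().endswith((".avi", ".mp4", ".mov")):
        frames = _read_video(path)
    else:
        frames = tifffile.imread(path)
        frames = np.asarray(frames)
        if frames.ndim == 2:
            frames = frames[None, ...]
        if frames.ndim != 3:
            bad = frames.shape
            raise ValidationError(
                f"unsupported TIFF layout {bad}: pages must be single-channel "
                "grayscale (got extra sample dimensions, e.g. RGB)"
            )
    if frames.shape[0] == 0:
        raise ValidationError("stack has zero frames")
    dt = _calibration(frames.shape[0], pixel_size_um, frame_interval_s, duration_s)
    return ImageStack(frames=frames, pixel_size_um=pixel_size_um, frame_interval_s=dt)


def _read_video(path: str) -> np.ndarray:
    try:
        import imageio.v3 as iio
    except ImportError as exc:  # pragma: no cover - depends on extras
        raise ValidationError(
            "AVI/video input requires the optional 'imageio' dependency "
            "(pip install chlamytrack[avi]); convert to multi-page TIFF otherwise"
        ) from exc
    try:
        frames = iio.imread(path)
    except Exception as exc:  # pragma: no cover - codec availability varies
        raise ValidationError(f"no decoder available for {path!r}: {exc}") from exc
    frames = np.asarray(frames)
    if frames.ndim == 4:
        if frames.shape[-1] not in (1, 3, 4):
            raise ValidationError(f"unsupported video layout {frames.shape}")
        if frames.shape[-1] == 1:
            frames = frames[..., 0]
        elif np.all(frames[..., 0] == frames[..., 1]) and np.all(frames[..., 1] == frames[..., 2]):
            frames = frames[..., 0]  # gray stored as RGB
        else:
            raise ValidationError("color video input is not supported; convert to grayscale")
    return frames
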