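"""Per-frame cell detection with a Laplacian-of-Gaussian blob detector.

Cells appear as near-circular bright blobs; convolving with the negated,
scale-normalized Laplacian of a Gaussian (``sigma**2 * -lap(G_sigma) * I``)
turns a blob of scale-space radius ``sigma*sqrt(2)`` into a positive local
maximum of the response at the blob center. Detections are the strict local
maxima of that response above a quality threshold, non-maximum-suppressed so
that no two detections fall closer than the expected radius, optionally
refined to sub-pixel precision by a quadratic fit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from scipy.spatial import cKDTree

from .errors import ConfigurationError, ValidationError
from .stack import ImageStack

__all__ = ["Spot", "DetectionConfig", "log_response", "detect_spots", "detect_stack"]


@dataclass(frozen=True)
class Spot:
    """One detected cell in one frame.

    Coordinates are sub-pixel pixel-center coordinates (x rightward,
    y downward); ``quality`` is the LoG response at the detection.
    """

    spot_id: int
    frame: int
    x_px: float
    y_px: float
    radius_px: float
    quality: float


@dataclass(frozen=True)
class DetectionConfig:
    """Two-knob detector interface: expected blob radius and quality cutoff.

    ``expected_radius_um`` is the physical blob radius (~5 µm for
    Chlamydomonas); the filter scale is derived from it as
    ``sigma_px = expected_radius_um / (pixel_size_um * sqrt(2))``.
    ``quality_threshold`` is in response units (same units as intensity).
    ``invert_intensity`` flips polarity for dark-on-bright (brightfield)
    input before filtering.
    """

    expected_radius_um: float = 5.0
    quality_threshold: float = 10.0
    do_subpixel: bool = True
    invert_intensity: bool = False

    def __post_init__(self) -> None:
        if self.expected_radius_um <= 0:
            raise ValidationError("expected_radius_um must be positive")

    def sigma_px(self, pixel_size_um: float) -> float:
        return self.expected_radius_um / (pixel_size_um * math.sqrt(2.0))


def log_response(frame: np.ndarray, sigma_px: float) -> np.ndarray:
    """Scale-normalized negated LoG response of one frame.

    Computes ``sigma**2 * -(lap(G_sigma) * I)`` with reflecting borders, so
    bright blobs of radius ``sigma*sqrt(2)`` produce positive local maxima
    and a constant image maps to (numerically) zero everywhere.
    """
    frame = np.asarray(frame, dtype=np.float64)
    if frame.ndim != 2:
        raise ValidationError(f"frame must be 2-D; got shape {frame.shape}")
    if not np.all(np.isfinite(frame)):
        raise ValidationError("frame contains non-finite pixels")
    if sigma_px <= 0:
        raise ValidationError("sigma_px must be positive")
    raw = -(sigma_px ** 2) * ndi.gaussian_laplace(frame, sigma_px, mode="reflect")
    # the sampled LoG kernel does not sum exactly to zero; subtract that DC
    # leakage (kernel sum x Gaussian-smoothed image) so constants map to 0
    dc = float(-(sigma_px ** 2) * ndi.gaussian_laplace(np.ones((1, 1)), sigma_px,
                                                      mode="reflect")[0, 0])
    return raw - dc * ndi.gaussian_filter(frame, sigma_px, mode="reflect")


def _strict_local_maxima(resp: np.ndarray, threshold: float) -> tuple[np.ndarray, np.ndarray]:
    """Pixels that are >= all 8 neighbours and above threshold.

    Plateau pixels all qualify here; the downstream non-maximum suppression
    keeps the lowest (y, x) of a plateau, which is the documented tie-break.
    """
    footprint = np.ones((3, 3), dtype=bool)
    maxf = ndi.maximum_filter(resp, footprint=footprint, mode="reflect")
    mask = (resp >= maxf) & (resp > threshold)
    ys, xs = np.nonzero(mask)
    return ys, xs


def _subpixel_offset(resp: np.ndarray, y: int, x: int) -> tuple[float, float]:
    """1-D quadratic (parabolic) refinement per axis, clamped to ±0.5 px."""
    h, w = resp.shape

    def axis_offset(m1: float, c0: float, p1: float) -> float:
        denom = m1 - 2.0 * c0 + p1
        if denom >= 0.0 or denom == 0.0:
            return 0.0
        off = 0.5 * (m1 - p1) / denom
        return float(np.clip(off, -0.5, 0.5))

    dy = axis_offset(resp[y - 1, x], resp[y, x], resp[y + 1, x]) if 0 < y < h - 1 else 0.0
    dx = axis_offset(resp[y, x - 1], resp[y, x], resp[y, x + 1]) if 0 < x < w - 1 else 0.0
    return dy, dx


def detect_spots(
    frame: np.ndarray,
    frame_index: int,
    config: DetectionConfig,
    pixel_size_um: float,
    id_start: int = 0,
) -> list[Spot]:
    """Detect blobs in one frame.

    Detections are strict local maxima of the LoG response above
    ``quality_threshold``, greedily non-maximum-suppressed (highest quality
    first, ties broken toward the lowest (y, x) pixel) so that no two spots
    lie closer than the expected radius. ``radius_px`` of every spot is
    ``sigma_px * sqrt(2)``. Spot ids are ``id_start, id_start+1, ...`` in
    quality order.
    """
    sigma = config.sigma_px(pixel_size_um)
    if sigma < 0.5:
        raise ConfigurationError(
            f"derived sigma {sigma:.3f} px < 0.5 px: expected radius below the "
            "detectable scale at this pixel size"
        )
    img = np.asarray(frame, dtype=np.float64)
    if config.invert_intensity:
        img = -img
    resp = log_response(img, sigma)
    ys, xs = _strict_local_maxima(resp, config.quality_threshold)
    if len(ys) == 0:
        return []
    q = resp[ys, xs]
    # highest quality first; (y, x) lexicographic among equal responses
    order = np.lexsort((xs, ys, -q))
    ys, xs, q = ys[order], xs[order], q[order]

    radius = sigma * math.sqrt(2.0)
    pts = np.column_stack([ys, xs]).astype(float)
    tree = cKDTree(pts)
    neighbours = tree.query_ball_point(pts, r=radius)
    kept: list[int] = []
    suppressed = np.zeros(len(ys), dtype=bool)
    for i in range(len(ys)):
        if suppressed[i]:
            continue
        kept.append(i)
        for j in neighbours[i]:
            if j != i and not suppressed[j]:
                # suppress only lower-priority candidates
                if j > i:
                    suppressed[j] = True

    spots: list[Spot] = []
    h, w = resp.shape
    for n, i in enumerate(kept):
        y, x = int(ys[i]), int(xs[i])
        if config.do_subpixel:
            dy, dx = _subpixel_offset(resp, y, x)
        else:
            dy = dx = 0.0
        spots.append(
            Spot(
                spot_id=id_start + n,
                frame=frame_index,
                x_px=min(max(x + dx, 0.0), w - 1.0),
                y_px=min(max(y + dy, 0.0), h - 1.0),
                radius_px=radius,
                quality=float(q[i]),
            )
        )
    return spots


def detect_stack(stack: ImageStack, config: DetectionConfig) -> list[list[Spot]]:
    """Run detection on every frame; spot ids are unique across the stack."""
    all_spots: list[list[Spot]] = []
    next_id = 0
    for t in range(stack.n_frames):
        spots = detect_spots(stack.frames[t], t, config, stack.pixel_size_um, id_start=next_id)
        next_id += len(spots)
        all_spots.append(spots)
    return all_spots
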