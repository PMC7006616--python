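"""Calibrated per-track speeds and population-level speed statistics.

Calibration is the single authority for unit conversion: positions in
pixels × ``pixel_size_um`` give µm, and the frame interval is the video
duration divided by the number of image slices. A track's mean speed is its
total path length divided by elapsed time (the "mean velocity" convention of
common tracking tools); the straight-line alternative is available as
``net_displacement_um / duration_s`` from the same record.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .errors import EmptyInputError, ValidationError
from .link import Track

__all__ = [
    "Calibration",
    "TrackStats",
    "PopulationSummary",
    "DEFAULT_BIN_EDGES_UM_S",
    "track_speed",
    "speed_histogram",
    "population_summary",
]

logger = logging.getLogger(__name__)

#: Default speed histogram bin edges (µm/s): a [0, 1) near-immotile bin, then
#: 10-µm/s-wide bins up to 101; speeds above the last edge fall into the
#: overflow bin appended by :func:`speed_histogram`.
DEFAULT_BIN_EDGES_UM_S: tuple[float, ...] = (0.0, 1.0, 11.0, 21.0, 31.0, 41.0,
                                             51.0, 61.0, 71.0, 81.0, 91.0, 101.0)


@dataclass(frozen=True)
class Calibration:
    """Pixel and time calibration of one video.

    ``frame_interval_s`` is derived as ``video_duration_s / n_frames``.
    """

    pixel_size_um: float
    video_duration_s: float
    n_frames: int

    def __post_init__(self) -> None:
        if self.pixel_size_um <= 0:
            raise ValidationError("pixel_size_um must be positive")
        if self.video_duration_s <= 0:
            raise ValidationError("video_duration_s must be positive")
        if self.n_frames < 1:
            raise ValidationError("n_frames must be >= 1")

    @property
    def frame_interval_s(self) -> float:
        return self.video_duration_s / self.n_frames

    @classmethod
    def from_interval(cls, pixel_size_um: float, frame_interval_s: float, n_frames: int) -> "Calibration":
        return cls(pixel_size_um=pixel_size_um,
                   video_duration_s=frame_interval_s * n_frames,
                   n_frames=n_frames)


@dataclass(frozen=True)
class TrackStats:
    """Per-track kinematics in physical units."""

    track_id: int
    n_spots: int
    duration_s: float
    path_length_um: float
    net_displacement_um: float
    mean_speed_um_s: float
    max_link_speed_um_s: float


def track_speed(track: Track, cal: Calibration) -> TrackStats:
    """Kinematic summary of one track.

    ``mean_speed_um_s = path_length_um / ((n_spots - 1) * frame_interval_s)``;
    the path length sums consecutive-spot displacements in µm, the net
    displacement is last spot minus first.
    """
    if track.n_spots < 2:
        raise ValidationError(
            f"track {track.track_id} has {track.n_spots} spot(s); speed is undefined "
            "for single-spot tracks"
        )
    xy = np.array([[s.x_px, s.y_px] for s in track.spots]) * cal.pixel_size_um
    steps = np.diff(xy, axis=0)
    d = np.hypot(steps[:, 0], steps[:, 1])
    dt = cal.frame_interval_s
    path = float(d.sum())
    net = float(math.hypot(*(xy[-1] - xy[0])))
    return TrackStats(
        track_id=track.track_id,
        n_spots=track.n_spots,
        duration_s=(track.end_frame - track.start_frame) * dt,
        path_length_um=path,
        net_displacement_um=net,
        mean_speed_um_s=path / ((track.n_spots - 1) * dt),
        max_link_speed_um_s=float(d.max()) / dt,
    )


def speed_histogram(
    stats: Sequence[TrackStats],
    bin_edges_um_s: Sequence[float] = DEFAULT_BIN_EDGES_UM_S,
) -> np.ndarray:
    """Fraction of tracks per speed bin.

    Bins are half-open ``[lo, hi)`` with the last regular bin closed; speeds
    strictly above the last edge land in an overflow bin appended at the end,
    so the returned vector has ``len(bin_edges) `` entries and always sums
    to 1.
    """
    if not stats:
        raise EmptyInputError("cannot histogram an empty track list")
    edges = np.asarray(bin_edges_um_s, dtype=float)
    if edges.ndim != 1 or edges.size < 2 or np.any(np.diff(edges) <= 0):
        raise ValidationError("bin edges must be strictly increasing with >= 2 values")
    speeds = np.array([s.mean_speed_um_s for s in stats])
    counts, _ = np.histogram(speeds[speeds <= edges[-1]], bins=edges)
    overflow = int(np.sum(speeds > edges[-1]))
    frac = np.append(counts, overflow) / len(speeds)
    return frac


@dataclass(frozen=True)
class PopulationSummary:
    """Speed statistics over one or more videos of one condition.

    ``mean_um_s`` is the mean of per-video mean track speeds; ``se_um_s`` is
    the sample standard deviation of the per-video means over √(n_videos),
    defined only for two or more videos (``nan`` otherwise).
    """

    n_videos: int
    n_tracks: int
    per_video_means_um_s: tuple[float, ...]
    mean_um_s: float
    se_um_s: float
    bin_edges_um_s: tuple[float, ...]
    histogram_fractions: tuple[float, ...]

    def summary(self) -> str:
        se = f"{self.se_um_s:.3g}" if np.isfinite(self.se_um_s) else "undefined (1 video)"
        lines = [
            f"Population speed summary ({self.n_videos} video(s), {self.n_tracks} tracks)",
            f"  mean of per-video means: {self.mean_um_s:.3g} um/s",
            f"  standard error:          {se}",
            "  histogram (um/s bin: fraction):",
        ]
        e = self.bin_edges_um_s
        for i, f in enumerate(self.histogram_fractions):
            label = f"[{e[i]:g}, {e[i + 1]:g})" if i < len(e) - 1 else f">{e[-1]:g}"
            lines.append(f"    {label:>12}: {f:.3f}")
        return "\n".join(lines)


def population_summary(
    per_video_stats: Sequence[Sequence[TrackStats]],
    bin_edges_um_s: Sequence[float] = DEFAULT_BIN_EDGES_UM_S,
    min_spots: int = 3,
) -> PopulationSummary:
    """Across-video mean ± standard error and a pooled speed histogram.

    Tracks shorter than ``min_spots`` detections are excluded. Videos left
    with zero eligible tracks are excluded from the across-video statistics
    with a logged warning.
    """
    if not per_video_stats:
        raise EmptyInputError("at least one video is required")
    kept: list[list[TrackStats]] = []
    for i, video in enumerate(per_video_stats):
        eligible = [s for s in video if s.n_spots >= min_spots]
        if not eligible:
            logger.warning("video %d has no tracks with >= %d spots; excluded", i, min_spots)
            continue
        kept.append(eligible)
    if not kept:
        raise EmptyInputError("no video has any eligible track")
    per_video_means = [float(np.mean([s.mean_speed_um_s for s in v])) for v in kept]
    pooled = [s for v in kept for s in v]
    mean = float(np.mean(per_video_means))
    se = (
        float(np.std(per_video_means, ddof=1) / math.sqrt(len(per_video_means)))
        if len(per_video_means) >= 2
        else float("nan")
    )
    frac = speed_histogram(pooled, bin_edges_um_s)
    return PopulationSummary(
        n_videos=len(kept),
        n_tracks=len(pooled),
        per_video_means_um_s=tuple(per_video_means),
        mean_um_s=mean,
        se_um_s=se,
        bin_edges_um_s=tuple(float(e) for e in bin_edges_um_s),
        histogram_fractions=tuple(float(f) for f in frac),
    )
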