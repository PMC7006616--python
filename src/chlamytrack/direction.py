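"""Track direction vectors and 8-sector occupancy ("rose plot") analysis.

Directional responses such as phototaxis are detected by dividing the
viewing area into eight sectors and asking whether the track coordinates
occupy them uniformly. Two sector geometries are supported:

* ``strips`` (default): eight equal-width vertical strips numbered 1–8 left
  to right — the geometry under which a left-to-right numbering is coherent;
* ``wedges``: eight 45° angular wedges about the field center, wedge 1
  centered on the −x direction, proceeding clockwise on screen (y down).

A complementary angular rose bins the *direction angles* of track net
displacements with the same numbering convention. Uniformity is summarized
by ``max_k |fraction_k − 1/K|`` together with its 3σ multinomial threshold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import EmptyInputError, ValidationError
from .link import Track
from .trackstats import Calibration

__all__ = [
    "DirectionVector",
    "SectorOccupancy",
    "BiasResult",
    "direction_vector",
    "direction_vectors",
    "sector_occupancy",
    "track_sector_occupancy",
    "angular_rose",
    "bias_statistic",
]

_TWO_PI = 2.0 * math.pi


@dataclass(frozen=True)
class DirectionVector:
    """Net displacement of one track in µm (x rightward, y downward).

    ``angle_rad`` is the atan2 heading of the net displacement; it is ``nan``
    (and ``has_angle`` False) for closed loops with zero magnitude.
    """

    track_id: int
    dx_um: float
    dy_um: float
    magnitude_um: float
    angle_rad: float

    @property
    def has_angle(self) -> bool:
        return self.magnitude_um > 0


@dataclass(frozen=True)
class SectorOccupancy:
    """Fraction of coordinates in each of ``n_sectors`` sectors."""

    n_sectors: int
    mode: str
    fractions: tuple[float, ...]
    n_points: int


@dataclass(frozen=True)
class BiasResult:
    """Uniformity summary: the occupancy statistic and its 3σ threshold."""

    statistic: float
    threshold: float

    @property
    def uniform(self) -> bool:
        return self.statistic <= self.threshold


def direction_vector(track: Track, cal: Calibration) -> DirectionVector:
    """Net displacement (last spot − first spot) of a track, in µm."""
    if track.n_spots < 2:
        raise ValidationError(
            f"track {track.track_id} has {track.n_spots} spot(s); direction is undefined"
        )
    first, last = track.spots[0], track.spots[-1]
    dx = (last.x_px - first.x_px) * cal.pixel_size_um
    dy = (last.y_px - first.y_px) * cal.pixel_size_um
    mag = math.hypot(dx, dy)
    angle = math.atan2(dy, dx) if mag > 0 else float("nan")
    return DirectionVector(track_id=track.track_id, dx_um=dx, dy_um=dy,
                           magnitude_um=mag, angle_rad=angle)


def direction_vectors(tracks: Sequence[Track], cal: Calibration) -> list[DirectionVector]:
    return [direction_vector(t, cal) for t in tracks if t.n_spots >= 2]


def _angle_bin(angles: np.ndarray, n_bins: int) -> np.ndarray:
    """0-based bin index; bin 0 centered on −x (angle π), clockwise (+angle)."""
    width = _TWO_PI / n_bins
    shifted = (angles - math.pi + width / 2.0) % _TWO_PI
    idx = np.floor(shifted / width).astype(int)
    return np.clip(idx, 0, n_bins - 1)


def sector_occupancy(
    coords: np.ndarray,
    field: tuple[float, float],
    n_sectors: int = 8,
    mode: str = "strips",
) -> SectorOccupancy:
    """Occupancy fractions of sectors of the viewing area.

    ``coords`` is an (N, 2) array of (x_px, y_px). In ``strips`` mode sector
    k (1-based) is the x-interval [(k−1)·W/K, k·W/K), last strip closed; in
    ``wedges`` mode sectors are equal angular wedges about the field center,
    wedge 1 centered on −x, proceeding clockwise.
    """
    if n_sectors < 2:
        raise ValidationError("n_sectors must be >= 2")
    if mode not in ("strips", "wedges"):
        raise ValidationError(f"mode must be 'strips' or 'wedges'; got {mode!r}")
    coords = np.atleast_2d(np.asarray(coords, dtype=float))
    if coords.size == 0:
        coords = coords.reshape(0, 2)
    if coords.shape[1] != 2:
        raise ValidationError("coords must have shape (N, 2)")
    w, h = field
    n = coords.shape[0]
    if n == 0:
        return SectorOccupancy(n_sectors=n_sectors, mode=mode,
                               fractions=(0.0,) * n_sectors, n_points=0)
    x, y = coords[:, 0], coords[:, 1]
    if np.any((x < 0) | (x > w) | (y < 0) | (y > h)):
        raise ValidationError("coordinates outside the field")
    if mode == "strips":
        idx = np.minimum((x / (w / n_sectors)).astype(int), n_sectors - 1)
    else:
        phi = np.arctan2(y - h / 2.0, x - w / 2.0)
        idx = _angle_bin(phi, n_sectors)
    counts = np.bincount(idx, minlength=n_sectors)
    return SectorOccupancy(
        n_sectors=n_sectors, mode=mode,
        fractions=tuple((counts / n).tolist()), n_points=n,
    )


def track_sector_occupancy(
    tracks: Sequence[Track],
    field: tuple[float, float],
    n_sectors: int = 8,
    mode: str = "strips",
    one_point_per_track: bool = False,
) -> SectorOccupancy:
    """Sector occupancy of the coordinates of all tracks.

    By default every spot coordinate of every track counts (time-weighted
    presence). With ``one_point_per_track`` each track contributes only its
    coordinate centroid — the variant to use when the multinomial uniformity
    bound must hold exactly, since per-frame coordinates of one cell are not
    independent draws.
    """
    pts: list[tuple[float, float]] = []
    for t in tracks:
        xy = [(s.x_px, s.y_px) for s in t.spots]
        if one_point_per_track:
            arr = np.asarray(xy)
            pts.append((float(arr[:, 0].mean()), float(arr[:, 1].mean())))
        else:
            pts.extend(xy)
    return sector_occupancy(np.asarray(pts).reshape(-1, 2), field, n_sectors, mode)


def angular_rose(vectors: Sequence[DirectionVector], n_bins: int = 8) -> np.ndarray:
    """Fractions of direction angles per angular bin.

    Bin 1 is centered on the −x direction, proceeding clockwise (same
    convention as wedge-mode sector occupancy). Zero-magnitude vectors have
    no angle and are ignored; if none remain the input is considered empty.
    """
    if n_bins < 2:
        raise ValidationError("n_bins must be >= 2")
    angles = np.array([v.angle_rad for v in vectors if v.has_angle])
    if angles.size == 0:
        raise EmptyInputError("no nonzero direction vectors to bin")
    idx = _angle_bin(angles, n_bins)
    return np.bincount(idx, minlength=n_bins) / angles.size


def bias_statistic(occupancy: SectorOccupancy) -> BiasResult:
    """Deviation of occupancy from uniformity, with a 3σ multinomial bound.

    The statistic is ``max_k |fraction_k − 1/K|``; the threshold is three
    multinomial standard deviations of a single fraction under uniformity,
    ``3·sqrt(p(1−p)/n)`` with ``p = 1/K`` — valid when the ``n_points``
    entries are independent draws.
    """
    if occupancy.n_points <= 0:
        raise EmptyInputError("occupancy has no points")
    p = 1.0 / occupancy.n_sectors
    stat = max(abs(f - p) for f in occupancy.fractions)
    thr = 3.0 * math.sqrt(p * (1.0 - p) / occupancy.n_points)
    return BiasResult(statistic=float(stat), threshold=float(thr))
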