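"""Frame-to-frame linking as a linear assignment problem.

Each consecutive frame pair defines a bipartite matching between the spots
of frame t and frame t+1 with squared Euclidean distance (µm²) as cost.
Candidate links farther than a gating distance are forbidden. The matrix is
augmented with per-spot "no-link" alternatives priced slightly above the
worst feasible link, so the problem is always feasible and spots may start
(birth) or end (death) a track. The augmented square problem is solved
exactly with the Hungarian (Munkres–Kuhn) algorithm.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment

from .detect import Spot
from .errors import InfeasibleAssignmentError, IntegrityError, ValidationError

__all__ = [
    "LinkingConfig",
    "Link",
    "Track",
    "default_gate_um",
    "build_cost_matrix",
    "solve_assignment",
    "link_frames",
    "build_tracks",
    "close_gaps",
]

#: Fastest track speed observed in the recordings this pipeline targets
#: (µm/s); used only to derive a generous default gating distance.
MAX_OBSERVED_SPEED_UM_S = 93.0

# exact lexicographic tie-break refinement is applied up to this matrix size
_LEX_REFINE_MAX_N = 64


def default_gate_um(frame_interval_s: float) -> float:
    """Default gating distance: 3× the per-frame step of the fastest swimmer."""
    return 3.0 * MAX_OBSERVED_SPEED_UM_S * frame_interval_s


@dataclass(frozen=True)
class LinkingConfig:
    """LAP linker parameters (TrackMate-style).

    ``max_link_distance_um`` gates candidate links; ``alternative_cost_factor``
    prices the no-link alternatives relative to the worst feasible link;
    gap closing is off by default (``max_gap_frames=0``).
    """

    max_link_distance_um: float
    alternative_cost_factor: float = 1.05
    max_gap_frames: int = 0
    max_gap_distance_um: Optional[float] = None

    def __post_init__(self) -> None:
        if self.max_link_distance_um <= 0:
            raise ValidationError("max_link_distance_um must be positive")
        if self.alternative_cost_factor <= 1.0:
            raise ValidationError("alternative_cost_factor must be > 1")
        if self.max_gap_frames < 0:
            raise ValidationError("max_gap_frames must be nonnegative")
        if self.max_gap_distance_um is None:
            object.__setattr__(self, "max_gap_distance_um", self.max_link_distance_um)
        elif self.max_gap_distance_um <= 0:
            raise ValidationError("max_gap_distance_um must be positive")


@dataclass(frozen=True)
class Link:
    """A directed link between two spots in increasing frames; cost in µm²."""

    spot_a_id: int
    spot_b_id: int
    cost: float


@dataclass(frozen=True)
class Track:
    """Time-ordered chain of spots attributed to one cell."""

    track_id: int
    spots: Sequence[Spot] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        object.__setattr__(self, "spots", tuple(self.spots))
        frames = [s.frame for s in self.spots]
        if any(b <= a for a, b in zip(frames, frames[1:])):
            raise ValidationError("track frames must be strictly increasing")

    @property
    def n_spots(self) -> int:
        return len(self.spots)

    @property
    def start_frame(self) -> int:
        return self.spots[0].frame

    @property
    def end_frame(self) -> int:
        return self.spots[-1].frame


def _pairwise_sq_um(a_xy: np.ndarray, b_xy: np.ndarray, pixel_size_um: float) -> np.ndarray:
    d = a_xy[:, None, :] - b_xy[None, :, :]
    return (d ** 2).sum(axis=2) * pixel_size_um ** 2


def build_cost_matrix(
    spots_t: Sequence[Spot],
    spots_t1: Sequence[Spot],
    config: LinkingConfig,
    pixel_size_um: float,
) -> np.ndarray:
    """Augmented (n+m)×(n+m) LAP cost matrix for one frame transition.

    Top-left n×m block: squared distances (µm²), ``inf`` beyond the gate.
    Diagonal top-right / bottom-left blocks: no-link (death/birth)
    alternatives priced at ``alternative_cost_factor`` × the largest feasible
    link cost (the squared gate if no link cost is positive). Bottom-right:
    zero wherever the transposed top-left entry is feasible, completing the
    square problem so a perfect assignment always exists.
    """
    n, m = len(spots_t), len(spots_t1)
    size = n + m
    mat = np.full((size, size), np.inf)
    gate2 = config.max_link_distance_um ** 2
    if n and m:
        a = np.array([[s.x_px, s.y_px] for s in spots_t])
        b = np.array([[s.x_px, s.y_px] for s in spots_t1])
        tl = _pairwise_sq_um(a, b, pixel_size_um)
        tl[tl > gate2] = np.inf
        mat[:n, :m] = tl
        finite = tl[np.isfinite(tl)]
        max_cost = float(finite.max()) if finite.size else 0.0
    else:
        max_cost = 0.0
    alt = config.alternative_cost_factor * (max_cost if max_cost > 0 else gate2)
    for i in range(n):
        mat[i, m + i] = alt
    for j in range(m):
        mat[n + j, j] = alt
    if n and m:
        mat[n:, m:][np.isfinite(mat[:n, :m]).T] = 0.0
    else:
        # no real-real block: the bottom-right corner is empty (size n+m is
        # covered entirely by the alternative diagonals)
        pass
    return mat


def _lsa_total(cost: np.ndarray) -> tuple[np.ndarray, float]:
    """linear_sum_assignment on a matrix that may contain inf (forbidden)."""
    if cost.size == 0:
        return np.empty(0, dtype=int), 0.0
    finite = cost[np.isfinite(cost)]
    if finite.size == 0:
        raise InfeasibleAssignmentError("no finite entries in cost matrix")
    big = max(float(finite.max()), 1.0) * cost.shape[0] * 1e6
    work = np.where(np.isfinite(cost), cost, big)
    rows, cols = linear_sum_assignment(work)
    if not np.all(np.isfinite(cost[rows, cols])):
        raise InfeasibleAssignmentError("no feasible perfect assignment exists")
    return cols[np.argsort(rows)], float(cost[rows, cols].sum())


def solve_assignment(cost_matrix: np.ndarray) -> tuple[list[tuple[int, int]], float]:
    """Minimum-cost perfect assignment of a square cost matrix.

    ``inf`` entries are forbidden. Among equally optimal assignments the
    lexicographically smallest matching (scanning rows in order, preferring
    the lowest column index) is returned for matrices up to 64×64; larger
    matrices return the (deterministic) solver output directly.

    Returns (pairs, total_cost) with pairs sorted by row index.
    """
    cost = np.asarray(cost_matrix, dtype=np.float64)
    if cost.ndim != 2 or cost.shape[0] != cost.shape[1]:
        raise ValidationError(f"cost matrix must be square; got shape {cost.shape}")
    nn = cost.shape[0]
    if nn == 0:
        return [], 0.0
    assign, total = _lsa_total(cost)

    if nn <= _LEX_REFINE_MAX_N:
        assign = _lexicographic_refine(cost, total)

    pairs = [(i, int(assign[i])) for i in range(nn)]
    return pairs, float(cost[np.arange(nn), assign].sum())


def _lexicographic_refine(cost: np.ndarray, total: float) -> np.ndarray:
    """Lexicographically smallest optimal assignment, by iterative fixing."""
    nn = cost.shape[0]
    tol = 1e-9 * max(abs(total), 1.0)
    remaining_cols = list(range(nn))
    assign = np.empty(nn, dtype=int)
    fixed_cost = 0.0
    sub = cost.copy()
    for i in range(nn):
        chosen = None
        for cj, j in enumerate(remaining_cols):
            if not np.isfinite(sub[0, cj]):
                continue
            rest = np.delete(np.delete(sub, 0, axis=0), cj, axis=1)
            if rest.size:
                try:
                    _, rest_total = _lsa_total(rest)
                except InfeasibleAssignmentError:
                    continue
            else:
                rest_total = 0.0
            if fixed_cost + sub[0, cj] + rest_total <= total + tol:
                chosen = (cj, j)
                break
        if chosen is None:  # numerically impossible if `total` is optimal
            raise InfeasibleAssignmentError("lexicographic refinement failed")
        cj, j = chosen
        assign[i] = j
        fixed_cost += sub[0, cj]
        remaining_cols.pop(cj)
        sub = np.delete(np.delete(sub, 0, axis=0), cj, axis=1)
    return assign


def link_frames(
    spots_by_frame: Sequence[Sequence[Spot]],
    config: LinkingConfig,
    pixel_size_um: float,
) -> list[Link]:
    """Link consecutive frames with the augmented LAP; returns real links only.

    Spots matched to a no-link alternative simply start or end a track.
    """
    links: list[Link] = []
    for t in range(len(spots_by_frame) - 1):
        a, b = spots_by_frame[t], spots_by_frame[t + 1]
        n, m = len(a), len(b)
        if n == 0 or m == 0:
            continue
        mat = build_cost_matrix(a, b, config, pixel_size_um)
        pairs, _ = solve_assignment(mat)
        for i, j in pairs:
            if i < n and j < m:
                links.append(Link(spot_a_id=a[i].spot_id, spot_b_id=b[j].spot_id,
                                  cost=float(mat[i, j])))
    return links


def build_tracks(links: Sequence[Link], spots_by_frame: Sequence[Sequence[Spot]]) -> list[Track]:
    """Assemble tracks as the connected chains of links.

    Singleton spots (no links) are not emitted. Track ids are assigned in
    order of (start frame, start y, start x).
    """
    by_id: dict[int, Spot] = {s.spot_id: s for frame in spots_by_frame for s in frame}
    succ: dict[int, int] = {}
    has_pred: set[int] = set()
    for lk in links:
        if lk.spot_a_id not in by_id or lk.spot_b_id not in by_id:
            raise IntegrityError(f"link references unknown spot: {lk}")
        if lk.spot_a_id in succ:
            raise IntegrityError(f"spot {lk.spot_a_id} has more than one outgoing link")
        if lk.spot_b_id in has_pred:
            raise IntegrityError(f"spot {lk.spot_b_id} has more than one incoming link")
        a, b = by_id[lk.spot_a_id], by_id[lk.spot_b_id]
        if b.frame <= a.frame:
            raise IntegrityError("link target frame must exceed source frame")
        succ[lk.spot_a_id] = lk.spot_b_id
        has_pred.add(lk.spot_b_id)

    chains: list[list[Spot]] = []
    for sid, spot in by_id.items():
        if sid in has_pred or sid not in succ:
            continue
        chain = [spot]
        cur = sid
        while cur in succ:
            cur = succ[cur]
            chain.append(by_id[cur])
        chains.append(chain)

    chains.sort(key=lambda c: (c[0].frame, c[0].y_px, c[0].x_px))
    return [Track(track_id=i, spots=c) for i, c in enumerate(chains)]


def close_gaps(
    tracks: Sequence[Track],
    config: LinkingConfig,
    pixel_size_um: float,
) -> list[Track]:
    """Second LAP stage joining track ends to later track starts.

    A track ending at frame t may be merged with a track starting within
    ``max_gap_frames`` frames and ``max_gap_distance_um`` distance; cost is
    the squared distance. With ``max_gap_frames=0`` (default) this is the
    identity.
    """
    if config.max_gap_frames < 1 or len(tracks) < 2:
        return list(tracks)

    n = len(tracks)
    gate2 = config.max_gap_distance_um ** 2
    tl = np.full((n, n), np.inf)
    for i, ti in enumerate(tracks):
        e = ti.spots[-1]
        for j, tj in enumerate(tracks):
            if i == j:
                continue
            s = tj.spots[0]
            dt = s.frame - e.frame
            if 1 <= dt <= 1 + config.max_gap_frames:
                d2 = ((s.x_px - e.x_px) ** 2 + (s.y_px - e.y_px) ** 2) * pixel_size_um ** 2
                if d2 <= gate2 and dt >= 2:  # dt == 1 would be a normal link, not a gap
                    tl[i, j] = d2
    finite = tl[np.isfinite(tl)]
    if finite.size == 0:
        return list(tracks)
    alt = config.alternative_cost_factor * float(finite.max() if finite.max() > 0 else gate2)
    mat = np.full((2 * n, 2 * n), np.inf)
    mat[:n, :n] = tl
    for i in range(n):
        mat[i, n + i] = alt
        mat[n + i, i] = alt
    mat[n:, n:][np.isfinite(tl).T] = 0.0
    pairs, _ = solve_assignment(mat)

    succ: dict[int, int] = {}
    merged_into: set[int] = set()
    for i, j in pairs:
        if i < n and j < n:
            succ[i] = j
            merged_into.add(j)

    out: list[list[Spot]] = []
    for i in range(n):
        if i in merged_into:
            continue
        spots = list(tracks[i].spots)
        cur = i
        while cur in succ:
            cur = succ[cur]
            spots.extend(tracks[cur].spots)
        out.append(spots)
    out.sort(key=lambda c: (c[0].frame, c[0].y_px, c[0].x_px))
    return [Track(track_id=i, spots=c) for i, c in enumerate(out)]


def relabel(track: Track, track_id: int) -> Track:
    return replace(track, track_id=track_id)
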