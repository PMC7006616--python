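"""Synthetic swimming-cell videos with exact ground-truth trajectories.

The simulator emulates dark-field time-lapse recordings of *Chlamydomonas*
cultures: near-circular bright cells on a dark background, recorded at
7.5 frames/s for about 30 s, with populations ranging from nearly immotile
mutants (~1.5 µm/s) to fast wild-type-like swimmers (~40–48 µm/s), optional
diad/tetrad aggregates and an optional directional light bias. Because every
trajectory is known exactly, simulator output serves as the oracle against
which detection, linking and the downstream statistics are validated.

Motion model
------------
Each cell (or rigid aggregate) performs a persistent random walk:

* a speed is drawn once per cell from the subpopulation's normal
  distribution truncated at zero and held constant for the whole clip;
* the heading starts uniform on [0, 2π) and is perturbed each frame by a
  normal increment with standard deviation ``heading_sd_rad``;
* cells under light bias first drift deterministically by up to
  ``bias_strength`` radians per frame toward the light direction (or
  directly away from it), then receive the random perturbation;
* boundaries are reflective, so no cell ever leaves the field and the
  number of trajectories is conserved.

Cells are rendered as isotropic Gaussian intensity bumps whose scale-space
radius equals ``cell_radius_px`` (i.e. the Gaussian standard deviation is
``cell_radius_px / sqrt(2)``), on a uniform background with additive
Gaussian read noise. Bright-on-dark is the default polarity; ``invert=True``
renders dark cells on a bright background (brightfield-like).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .errors import UnknownStrainError, ValidationError
from .stack import ImageStack

__all__ = [
    "SubPop",
    "LightBias",
    "SimScenario",
    "GroundTruth",
    "simulate_population",
    "simulate_trajectories",
    "render_frame",
    "strain_preset",
    "available_strains",
    "STRAIN_SPEEDS_UM_S",
]

#: Published mean swimming speeds (µm/s) ± standard error for the wild-type
#: strain cc124, twelve motility mutants, and the related species
#: C. moewusii. Values are (mean, se).
STRAIN_SPEEDS_UM_S: dict[str, tuple[float, float]] = {
    "cc124": (40.0, 4.5),    # wild type
    "cc125": (46.0, 2.0),    # phototactic aggregation
    "cc602": (2.8, 0.6),     # pf1, no radial spoke heads
    "cc1026": (9.0, 5.0),    # pf3, axonemal protein defects
    "cc1032": (3.5, 0.1),    # pf14, lacks radial spokes
    "cc1036": (1.5, 0.7),    # pf18, no central microtubules
    "cc1926": (15.0, 3.0),   # uni1, single flagellum
    "cc2228": (11.0, 2.0),   # oda1, lacks outer dynein arms
    "cc2288": (32.0, 1.0),   # lf2-4, long flagella
    "cc2530": (4.0, 2.0),    # vfl2, 0-6 flagella
    "cc2670": (14.0, 2.0),   # ida4, dynein arms
    "cc2679": (3.4, 0.6),    # mbo1, flagellar axoneme
    "cc3663": (22.0, 2.25),  # shf1, short flagella
    "moewusii": (48.0, 6.0), # C. moewusii
}


@dataclass(frozen=True)
class SubPop:
    """One subpopulation of swimmers (typically one strain).

    ``heading_sd_rad`` is the per-frame standard deviation of the random
    heading perturbation: 0 gives perfectly straight swimmers.
    """

    label: str
    fraction: float = 1.0
    mean_speed_um_s: float = 40.0
    speed_sd_um_s: float = 0.0
    heading_sd_rad: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.fraction <= 1.0:
            raise ValidationError(f"fraction must be in [0, 1]; got {self.fraction}")
        if self.mean_speed_um_s < 0 or self.speed_sd_um_s < 0:
            raise ValidationError("speeds must be nonnegative")
        if self.heading_sd_rad < 0:
            raise ValidationError("heading_sd_rad must be nonnegative")


@dataclass(frozen=True)
class LightBias:
    """Directional light stimulus.

    ``light_angle_rad`` is the heading (image coordinates, x rightward,
    y downward) pointing *toward* the light source. A ``toward_fraction``
    of cells drift toward that heading, an ``away_fraction`` drift toward
    the opposite heading, and the remainder swim unbiased — mirroring the
    bidirectional phototactic response in which cells orient both into the
    beam path and away from the source.
    """

    light_angle_rad: float = 0.0
    toward_fraction: float = 0.5
    away_fraction: float = 0.5
    bias_strength: float = 0.3

    def __post_init__(self) -> None:
        for name in ("toward_fraction", "away_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must be in [0, 1]; got {v}")
        if self.toward_fraction + self.away_fraction > 1.0 + 1e-9:
            raise ValidationError("toward_fraction + away_fraction must not exceed 1")
        if self.bias_strength < 0:
            raise ValidationError("bias_strength must be nonnegative")


@dataclass(frozen=True)
class SimScenario:
    """Full specification of one synthetic video.

    Defaults reproduce the acquisition geometry the package targets:
    7.5 frames/s for 30 s (225 frames), 1 µm pixels, cells of ~5 µm radius.
    """

    field_width_px: int = 512
    field_height_px: int = 512
    n_cells: int = 100
    n_frames: int = 225
    frame_interval_s: float = 1.0 / 7.5
    pixel_size_um: float = 1.0
    subpopulations: Sequence[SubPop] = field(default_factory=lambda: (SubPop("cc124", 1.0, 40.0, 4.5, 0.2),))
    aggregate_fraction: float = 0.0
    light_bias: Optional[LightBias] = None
    background_level: float = 100.0
    noise_sd: float = 0.0
    cell_radius_px: float = 5.0
    cell_intensity: float = 1000.0
    min_separation_px: float = 0.0
    invert: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "subpopulations", tuple(self.subpopulations))
        if self.field_width_px <= 0 or self.field_height_px <= 0:
            raise ValidationError("field dimensions must be positive (zero-area field)")
        if self.n_frames < 1:
            raise ValidationError("n_frames must be >= 1")
        if self.n_cells < 0:
            raise ValidationError("n_cells must be nonnegative")
        if self.frame_interval_s <= 0 or self.pixel_size_um <= 0:
            raise ValidationError("frame_interval_s and pixel_size_um must be positive")
        if self.cell_radius_px <= 0:
            raise ValidationError("cell_radius_px must be positive")
        if not 0.0 <= self.aggregate_fraction <= 1.0:
            raise ValidationError("aggregate_fraction must be in [0, 1]")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be nonnegative")
        if self.min_separation_px < 0:
            raise ValidationError("min_separation_px must be nonnegative")
        if not self.subpopulations:
            raise ValidationError("at least one subpopulation is required")
        total = sum(p.fraction for p in self.subpopulations)
        if abs(total - 1.0) > 1e-9:
            raise ValidationError(f"subpopulation fractions must sum to 1; got {total}")

    @property
    def duration_s(self) -> float:
        return self.n_frames * self.frame_interval_s


@dataclass(frozen=True)
class GroundTruth:
    """Exact trajectories of all simulated cells.

    ``positions`` has shape ``(n_cells, n_frames, 2)`` holding (x_px, y_px);
    ``group_id`` marks aggregate membership (singletons get their own id),
    ``group_size`` is 1, 2 or 4, and ``bias_class`` is ``"toward"``,
    ``"away"`` or ``"none"``.
    """

    positions: np.ndarray
    labels: tuple[str, ...]
    speeds_um_s: np.ndarray
    group_id: np.ndarray
    group_size: np.ndarray
    bias_class: tuple[str, ...]
    pixel_size_um: float
    frame_interval_s: float

    @property
    def n_cells(self) -> int:
        return self.positions.shape[0]

    @property
    def n_frames(self) -> int:
        return self.positions.shape[1] if self.n_cells else 0

    def empirical_speeds_um_s(self) -> np.ndarray:
        """Mean frame-to-frame displacement per cell, converted to µm/s."""
        if self.n_cells == 0:
            return np.empty(0)
        steps = np.diff(self.positions, axis=1)
        d = np.hypot(steps[..., 0], steps[..., 1])
        return d.mean(axis=1) * self.pixel_size_um / self.frame_interval_s

    def net_displacement_angles(self) -> np.ndarray:
        """atan2 heading of each cell's net displacement (image coordinates)."""
        if self.n_cells == 0:
            return np.empty(0)
        net = self.positions[:, -1, :] - self.positions[:, 0, :]
        return np.arctan2(net[:, 1], net[:, 0])

    def to_dataframe(self):
        """Long-format table: one row per cell per frame."""
        import pandas as pd

        n, t = self.n_cells, self.n_frames
        return pd.DataFrame(
            {
                "cell_id": np.repeat(np.arange(n), t),
                "label": np.repeat(np.asarray(self.labels, dtype=object), t),
                "group_id": np.repeat(self.group_id, t),
                "frame": np.tile(np.arange(t), n),
                "x_px": self.positions[..., 0].ravel(),
                "y_px": self.positions[..., 1].ravel(),
                "true_speed_um_s": np.repeat(self.speeds_um_s, t),
            }
        )

    def to_tracks(self, radius_px: float = 5.0) -> list:
        """Convert trajectories to :class:`~chlamytrack.link.Track` objects.

        Lets the direction/statistics layers run directly on ground truth,
        bypassing detection and linking.
        """
        from .detect import Spot
        from .link import Track

        tracks = []
        spot_id = 0
        for cid in range(self.n_cells):
            spots = []
            for f in range(self.n_frames):
                x, y = self.positions[cid, f]
                spots.append(Spot(spot_id=spot_id, frame=f, x_px=float(x), y_px=float(y),
                                  radius_px=radius_px, quality=1.0))
                spot_id += 1
            tracks.append(Track(track_id=cid, spots=spots))
        return tracks


def _largest_remainder_counts(fractions: np.ndarray, total: int) -> np.ndarray:
    """Apportion `total` items to classes with given fractions, deterministically."""
    raw = fractions * total
    counts = np.floor(raw).astype(int)
    short = total - counts.sum()
    if short > 0:
        order = np.argsort(-(raw - counts), kind="stable")
        counts[order[:short]] += 1
    return counts


def _group_offsets(size: int, radius_px: float, angle: float) -> np.ndarray:
    """Rigid member offsets (relative to the group centroid) for aggregates.

    Diads sit at ±radius along a random fixed axis; tetrads on the corners of
    a square of side 2·radius. All members stay within 2·radius of the
    centroid.
    """
    if size == 1:
        return np.zeros((1, 2))
    if size == 2:
        u = np.array([math.cos(angle), math.sin(angle)])
        return np.stack([radius_px * u, -radius_px * u])
    if size == 4:
        c, s = math.cos(angle), math.sin(angle)
        rot = np.array([[c, -s], [s, c]])
        corners = radius_px * np.array([[1, 1], [1, -1], [-1, 1], [-1, -1]], dtype=float)
        return corners @ rot.T
    raise ValidationError(f"unsupported aggregate size {size}")


def _wrap_angle(a: float) -> float:
    return (a + math.pi) % (2.0 * math.pi) - math.pi


def simulate_trajectories(scenario: SimScenario) -> GroundTruth:
    """Draw the ground-truth trajectories of a scenario (no rendering).

    Deterministic: the same scenario (including its seed) always yields the
    identical trajectories.
    """
    rng = np.random.default_rng(scenario.seed)
    n = scenario.n_cells
    t = scenario.n_frames
    w, h = scenario.field_width_px, scenario.field_height_px
    r = scenario.cell_radius_px

    if n == 0:
        return GroundTruth(
            positions=np.empty((0, max(t, 0), 2)),
            labels=(), speeds_um_s=np.empty(0), group_id=np.empty(0, dtype=int),
            group_size=np.empty(0, dtype=int), bias_class=(),
            pixel_size_um=scenario.pixel_size_um,
            frame_interval_s=scenario.frame_interval_s,
        )

    fractions = np.array([p.fraction for p in scenario.subpopulations])
    counts = _largest_remainder_counts(fractions, n)

    # Build groups: within each subpopulation, aggregate_fraction of the cells
    # are placed in rigid aggregates, the aggregated budget split as evenly as
    # possible between tetrads and diads; the remainder swim as singletons.
    groups: list[tuple[int, int]] = []  # (subpop index, group size)
    for k, nk in enumerate(counts):
        budget = int(round(scenario.aggregate_fraction * nk))
        n_tet = (budget // 2) // 4
        rem = budget - 4 * n_tet
        n_diad = rem // 2
        n_single = nk - 4 * n_tet - 2 * n_diad
        groups += [(k, 4)] * n_tet + [(k, 2)] * n_diad + [(k, 1)] * n_single

    n_groups = len(groups)

    # Light-bias class per group, again by largest-remainder apportionment so
    # that population composition is exact rather than binomially noisy.
    bias_of_group = ["none"] * n_groups
    if scenario.light_bias is not None:
        lb = scenario.light_bias
        cls_counts = _largest_remainder_counts(
            np.array([lb.toward_fraction, lb.away_fraction]), n_groups
        )
        i = 0
        for cls, c in zip(("toward", "away"), cls_counts):
            for _ in range(c):
                bias_of_group[i] = cls
                i += 1

    dt = scenario.frame_interval_s
    px = scenario.pixel_size_um

    positions = np.empty((n, t, 2))
    speeds = np.empty(n)
    labels: list[str] = []
    group_id = np.empty(n, dtype=int)
    group_size = np.empty(n, dtype=int)
    bias_class: list[str] = []

    cell = 0
    placed: list[np.ndarray] = []
    for gid, (k, size) in enumerate(groups):
        pop = scenario.subpopulations[k]
        # speed: normal truncated at 0 via resampling
        speed = rng.normal(pop.mean_speed_um_s, pop.speed_sd_um_s) if pop.speed_sd_um_s > 0 else pop.mean_speed_um_s
        while speed < 0:
            speed = rng.normal(pop.mean_speed_um_s, pop.speed_sd_um_s)
        step_px = speed * dt / px

        offsets = _group_offsets(size, r, rng.uniform(0.0, 2.0 * math.pi))
        margin = float(np.max(np.hypot(offsets[:, 0], offsets[:, 1])))
        # keep the centroid inside [margin, extent-1-margin] so every member
        # stays within the field even at a bounce
        lo = np.array([margin, margin])
        hi = np.array([w - 1.0 - margin, h - 1.0 - margin])
        if np.any(hi <= lo):
            raise ValidationError("field too small for the requested aggregate size")

        # initial placement, optionally rejection-sampled so group centroids
        # start at least min_separation_px apart (Poisson-disk style)
        pos = rng.uniform(lo, hi)
        if scenario.min_separation_px > 0 and placed:
            ok = False
            for _ in range(10_000):
                d = np.hypot(*(np.asarray(placed) - pos).T)
                if d.min() >= scenario.min_separation_px:
                    ok = True
                    break
                pos = rng.uniform(lo, hi)
            if not ok:
                raise ValidationError(
                    "could not place all groups with the requested min_separation_px"
                )
        placed.append(pos.copy())
        theta = rng.uniform(0.0, 2.0 * math.pi)
        bias = bias_of_group[gid]

        centroid = np.empty((t, 2))
        centroid[0] = pos
        for f in range(1, t):
            if bias != "none":
                target = scenario.light_bias.light_angle_rad
                if bias == "away":
                    target += math.pi
                delta = _wrap_angle(target - theta)
                strength = scenario.light_bias.bias_strength
                theta += np.clip(delta, -strength, strength)
            if pop.heading_sd_rad > 0:
                theta += rng.normal(0.0, pop.heading_sd_rad)
            vx, vy = step_px * math.cos(theta), step_px * math.sin(theta)
            nxt = pos + (vx, vy)
            # reflective boundaries; reflect the velocity so persistence
            # carries the cell away from the wall
            for ax in range(2):
                span = hi[ax] - lo[ax]
                p = nxt[ax] - lo[ax]
                p = p % (2.0 * span)
                if p > span:
                    p = 2.0 * span - p
                    if ax == 0:
                        vx = -vx
                    else:
                        vy = -vy
                nxt[ax] = p + lo[ax]
            theta = math.atan2(vy, vx) if step_px > 0 else theta
            pos = nxt
            centroid[f] = pos

        for m in range(size):
            positions[cell] = centroid + offsets[m]
            speeds[cell] = speed
            labels.append(pop.label)
            group_id[cell] = gid
            group_size[cell] = size
            bias_class.append(bias)
            cell += 1

    return GroundTruth(
        positions=positions, labels=tuple(labels), speeds_um_s=speeds,
        group_id=group_id, group_size=group_size, bias_class=tuple(bias_class),
        pixel_size_um=px, frame_interval_s=dt,
    )


def render_frame(
    positions: Sequence[tuple[float, float, float]],
    scenario: SimScenario,
    rng: Optional[np.random.Generator] = None,
) -> np.ndarray:
    """Render one frame: Gaussian bumps on a noisy uniform background.

    Each ``(x_px, y_px, radius_px)`` entry becomes an isotropic Gaussian of
    standard deviation ``radius_px / sqrt(2)`` (so its scale-space radius is
    ``radius_px``) and peak amplitude ``cell_intensity`` added to (or, with
    ``invert=True``, subtracted from) ``background_level``. Noise is i.i.d.
    Gaussian with sd ``noise_sd``; pass ``rng`` for reproducible noise.
    Returns a float64 image; quantization to uint16 happens at stack
    assembly/writing time.
    """
    w, h = scenario.field_width_px, scenario.field_height_px
    img = np.full((h, w), float(scenario.background_level))
    sign = -1.0 if scenario.invert else 1.0
    for x, y, radius in positions:
        sd = radius / math.sqrt(2.0)
        half = max(1, int(math.ceil(4.0 * sd)))
        x0, x1 = int(math.floor(x)) - half, int(math.floor(x)) + half + 1
        y0, y1 = int(math.floor(y)) - half, int(math.floor(y)) + half + 1
        x0c, x1c = max(x0, 0), min(x1, w)
        y0c, y1c = max(y0, 0), min(y1, h)
        if x0c >= x1c or y0c >= y1c:
            continue
        xs = np.arange(x0c, x1c) - x
        ys = np.arange(y0c, y1c) - y
        g = np.exp(-(ys[:, None] ** 2 + xs[None, :] ** 2) / (2.0 * sd * sd))
        img[y0c:y1c, x0c:x1c] += sign * scenario.cell_intensity * g
    if scenario.noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng(scenario.seed)
        img += rng.normal(0.0, scenario.noise_sd, size=img.shape)
    return img


def _quantize(img: np.ndarray) -> np.ndarray:
    return np.clip(np.rint(img), 0, 65535).astype(np.uint16)


def simulate_population(scenario: SimScenario) -> tuple[ImageStack, GroundTruth]:
    """Simulate a full video: rendered 16-bit stack plus exact trajectories.

    Bit-for-bit reproducible for a fixed scenario (trajectories are drawn
    first, then per-frame noise, from a single seeded generator).
    """
    truth = simulate_trajectories(scenario)
    rng = np.random.default_rng(np.random.SeedSequence([scenario.seed, 1]))
    frames = np.empty(
        (scenario.n_frames, scenario.field_height_px, scenario.field_width_px),
        dtype=np.uint16,
    )
    r = scenario.cell_radius_px
    for f in range(scenario.n_frames):
        if truth.n_cells:
            pos = [(truth.positions[c, f, 0], truth.positions[c, f, 1], r)
                   for c in range(truth.n_cells)]
        else:
            pos = []
        frames[f] = _quantize(render_frame(pos, scenario, rng=rng))
    stack = ImageStack(frames=frames, pixel_size_um=scenario.pixel_size_um,
                       frame_interval_s=scenario.frame_interval_s)
    return stack, truth


def available_strains() -> tuple[str, ...]:
    return tuple(STRAIN_SPEEDS_UM_S)


def strain_preset(strain_id: str, fraction: float = 1.0, heading_sd_rad: float = 0.2) -> SubPop:
    """Subpopulation preset with the published mean speed of a strain.

    The speed spread defaults to the published ± (standard error) value for
    the strain; within-strain per-cell variance was not reported, so treat
    ``speed_sd_um_s`` as a free parameter when it matters.
    """
    try:
        mean, sd = STRAIN_SPEEDS_UM_S[strain_id]
    except KeyError:
        raise UnknownStrainError(
            f"unknown strain {strain_id!r}; valid ids: {', '.join(STRAIN_SPEEDS_UM_S)}"
        ) from None
    return SubPop(label=strain_id, fraction=fraction, mean_speed_um_s=mean,
                  speed_sd_um_s=sd, heading_sd_rad=heading_sd_rad)


def scenario_replace(scenario: SimScenario, **kw) -> SimScenario:
    """Return a copy of ``scenario`` with the given fields replaced."""
    return replace(scenario, **kw)
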