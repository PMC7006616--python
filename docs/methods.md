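# Methods

This note records the models, conventions and numerical choices behind
`chlamytrack`, and what the simulator-based validation does and does not
establish about real recordings.

## The tracking model

**Detection.** Cells are modeled as isotropic bright (or, inverted, dark)
blobs. A frame is convolved with the scale-normalized negated Laplacian of
Gaussian, `R = σ²·(−∇²G_σ ∗ I)`, with reflecting borders. A Gaussian blob
of standard deviation `s` produces its strongest center response at the
matched scale `σ = s`, where the center value is half the blob amplitude —
a useful rule of thumb when choosing a quality threshold. The filter scale
derives from the physical radius knob as
`σ_px = expected_radius_um / (pixel_size_um·√2)`, and each detection is
reported with `radius_px = σ·√2` (the scale-space radius). The sampled LoG
kernel does not sum exactly to zero; the residual (kernel sum × smoothed
image) is subtracted so that constant images map to exactly zero response
and thresholds are background-independent.

Detections are the strict local maxima of `R` above `quality_threshold`,
greedily non-maximum-suppressed (highest response first, plateau ties broken
toward the lowest `(y, x)` pixel — a documented, reproducible convention) so
that no two spots lie closer than the expected radius. This separation is
what resolves diad/tetrad aggregate members, whose centers sit two radii
apart. Sub-pixel refinement fits a 1-D parabola per axis through the 3×3
response neighborhood, clamped to ±0.5 px; it is on by default. Scales
below σ = 0.5 px are rejected as undetectable.

**Linking.** For each consecutive frame pair, candidate links are priced at
squared Euclidean displacement in µm²; links farther than
`max_link_distance_um` are forbidden. The default gate is three times the
per-frame step of the fastest swimmer this pipeline targets (≈93 µm/s), i.e.
`3·93·Δt` µm — generous enough never to gate a plausible link, tight enough
to keep the problem sparse. The n×m candidate block is embedded in an
(n+m)×(n+m) matrix with diagonal "death"/"birth" alternatives priced at
`alternative_cost_factor` (default 1.05) × the largest feasible link cost
(the squared gate when every candidate cost is zero, so that real links are
still strictly preferred), and a lower-right completion block of zeros where
the transposed candidate is feasible. The augmented problem always has a
perfect assignment, so births and deaths fall out of the same exact solve.

The solve itself uses `scipy.optimize.linear_sum_assignment`. Among equally
optimal assignments the lexicographically smallest matching (scanning rows
in order, preferring the lowest column) is returned; this refinement is
computed exactly — by fixing one row at a time and re-solving the remainder —
for matrices up to 64×64, which covers every tie-prone case in practice
(ties come from the identical alternative prices and the zero completion
block, not from generic float distances). Larger matrices return the
solver's deterministic output directly. Tests validate optimality against an
exhaustive-permutation oracle up to 6×6.

Gap closing is a second assignment between track ends and track starts
separated by 2…`max_gap_frames`+1 frames within `max_gap_distance_um`, again
with squared-distance costs and priced alternatives. It is **off by
default** (`max_gap_frames = 0`); dropouts are rare at the default detection
settings and fragments are unbiased speed samples.

**Speeds and calibration.** `Calibration` is the single unit-conversion
authority: `frame_interval_s = video_duration_s / n_frames`, positions ×
`pixel_size_um`. A track's mean speed is total path length over elapsed
time, `Σ|Δx| / ((n_spots−1)·Δt)` — the "mean velocity" convention of common
tracking software; net displacement over duration is also reported so users
can compare the two. Tracks need ≥ 2 spots for a speed and, by default,
≥ 3 spots (`min_spots`) to enter population statistics — two-spot tracks
are the most likely to be spurious link artifacts. Across-video statistics
are the mean of per-video mean track speeds with
`SE = sd(per-video means)/√n_videos`; SE is undefined (NaN) for a single
video, and videos with no eligible tracks are dropped with a logged
warning.

**Histogram bins.** The default speed bin edges are
`0, 1, 11, 21, …, 101` µm/s: a `[0, 1)` near-immotile bin, then 10-µm/s-wide
bins, plus an overflow bin above the last edge so fractions always sum to 1.
Published speed-range phrasings for this kind of data ("21–40", "31–60",
"51–75 µm/s") cannot all come from one partition, so the edges are fully
configurable and the default is a single regular convention. Bins are
half-open `[lo, hi)` with the last regular bin closed.

**Directionality.** The viewing area is divided into 8 sectors in either of
two geometries: vertical **strips** numbered 1–8 left to right (the default —
the only geometry in which a left-to-right numbering is coherent), or 45°
**wedges** about the field center with wedge 1 centered on −x, proceeding
clockwise on screen (y points down). Occupancy counts every spot coordinate
of every track by default (time-weighted presence); the
`one_point_per_track` variant uses each track's centroid instead. The
uniformity statistic is `max_k |f_k − 1/8|` compared against three
multinomial standard deviations, `3·√(p(1−p)/n)` with `p = 1/8`. That bound
assumes independent draws, which per-frame coordinates of one cell are not —
consecutive positions of a swimming cell are strongly autocorrelated, so
all-coordinate occupancy exceeds the bound even for unbiased populations.
Uniformity testing should therefore use the centroid variant (one
independent-ish point per cell), and the validation suite does; the
all-coordinate mode remains the right choice for visualizing where cells
spend time. The angular rose bins track net-displacement headings with the
same numbering convention; zero-magnitude vectors (closed loops) have no
angle and are excluded.

## The simulator

The simulator emulates the recordings this pipeline targets: ~7.5 frames/s
for ~30 s (defaults: 225 frames, Δt = 1/7.5 s), 1 µm pixels, a 512×512
field, cells of ~5 µm radius, populations from near-immotile (~1.5 µm/s) to
fast wild-type-like (~40–48 µm/s) swimmers. Strain presets carry the
published mean ± SE speeds for cc124, twelve motility mutants and
*C. moewusii*.

Motion is a persistent random walk: per-cell speed drawn once from the
subpopulation's normal truncated at zero (resampling), constant thereafter;
heading initialized uniformly and perturbed each frame by
`N(0, heading_sd_rad²)`; boundaries reflective, with the velocity component
reflected too so persistence carries cells off walls. Light bias adds, per
biased cell and before the random perturbation, a deterministic heading
drift of up to `bias_strength` rad/frame toward the light direction
(`toward` cells) or directly away from it (`away` cells) — a bidirectional
scheme that reproduces populations orienting both into a beam path and away
from the source. Subpopulation and bias-class counts are apportioned by
largest remainder, so a "50:50 mixture" is exactly 50:50 rather than
binomially noisy. Aggregates (diads/tetrads) are rigid groups — members at
fixed offsets (±r for diads, a 2r-square for tetrads, all within 2r of the
centroid) around one walking centroid. Optional Poisson-disk-style initial
placement (`min_separation_px`) supports scenarios whose contracts require
well-separated cells.

Rendering draws each cell as a Gaussian bump of standard deviation
`radius/√2` (so its scale-space radius equals the nominal cell radius, and
the detector's radius knob means the same thing as the simulator's), peak
amplitude `cell_intensity` (default 1000 counts) on `background_level`
(default 100), plus i.i.d. Gaussian read noise; frames are quantized to
16-bit. One seeded generator drives trajectories first, then per-frame
noise, so a scenario is bit-for-bit reproducible.

**What the simulator does not emulate** — and hence what passing tests do
not establish about real videos: optical blur beyond the Gaussian-blob
shape (no point-spread asymmetry, no defocus as cells drift in z), cells
entering or leaving the field, cell–cell collisions or hydrodynamic
interactions, intensity variation between cells, flagellar-beat wobble
around the body centroid, illumination gradients, and compression
artifacts. Real-data performance still depends on choosing a sensible
radius and threshold for the actual optics.

## Validation design and problem sizes

The validation suite runs entirely on simulated ground truth, at sizes
chosen to exercise each contract well inside a desktop run: 200 random
matrices (≤ 6×6) against the brute-force assignment oracle; 80-cell frames
(noiseless and 2%-of-amplitude noise) for detection recall/precision
(≥ 0.99) and localization (≤ 0.5 px); a 20-cell, 225-frame clip of slow
wiggly swimmers kept ≥ 80 px apart for exact trajectory recovery; 30-cell,
50-frame scenarios for speed recovery at 5–80 µm/s (within 5%) and for the
strictly-increasing strain ordering cc1036 < cc2228 < cc3663 < cc124; a
60-cell 50:50 mixture (15 vs 45 µm/s) for histogram bimodality; and 100
seeded 600-cell runs for the uniformity Monte-Carlo (≥ 95 expected to pass
the 3σ check; light-biased runs must fail it and load the entry strip and
the three far strips). Trajectory *identity* in the fidelity check uses a
2.5 px (half cell radius) matching tolerance — identity is unambiguous when
cells stay tens of pixels apart — while mean localization must still be
sub-pixel; cells riding the field wall have their blobs clipped and
localize ~0.5–1 px off, which is a rendering-boundary effect, not a linker
error.

## Known limitations

* The lexicographic tie-break is exact only up to 64×64 matrices; beyond
  that, equal-cost optima resolve to the solver's deterministic but
  unspecified choice. Link sets on generic data are unaffected.
* Reflection shortens the sampled displacement in the bounce frame, so
  empirical ground-truth speeds sit a hair below the assigned speed for
  cells that hit walls; tests account for this.
* Gap closing merges at most chains of fragments pairwise per stage; long
  repeated dropouts of the same cell need `max_gap_frames` large enough to
  bridge each individual gap.
* The CSV tables use TrackMate-style column names as a compatibility goal
  for downstream scripts; no byte-level compatibility with any specific
  TrackMate version is claimed.
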