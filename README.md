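# chlamytrack

Automated motility tracking for *Chlamydomonas* time-lapse microscopy.

Populations of swimming unicellular algae such as *Chlamydomonas
reinhardtii* respond to light, nutrients and mutation with changes in
swimming speed and direction. Characterizing those responses requires
following hundreds to thousands of cells per 30-second video — far beyond
manual tracking. `chlamytrack` implements the complete analysis chain for
such recordings:

1. **Detection** — each frame is filtered with a scale-normalized
   Laplacian-of-Gaussian (LoG) kernel, `σ²·(−∇²G_σ ∗ I)`, whose strict
   local maxima above a quality threshold localize near-circular cells to
   sub-pixel precision (quadratic refinement), including individual members
   of diad/tetrad aggregates.
2. **Linking** — consecutive frames define a linear assignment problem
   (LAP) with squared displacement (µm²) as cost, gated by a maximum link
   distance and augmented with priced "no-link" alternatives for track
   births and deaths; the augmented square problem is solved exactly with
   the Hungarian (Munkres–Kuhn) algorithm. An optional second LAP stage
   closes short detection gaps.
3. **Statistics** — calibrated per-track speeds
   (`v̄ = path length / elapsed time`, with the frame interval computed as
   video duration / number of slices), per-video means, across-video
   mean ± standard error, and binned speed histograms that resolve mixed
   populations.
4. **Directionality** — per-track net-displacement vectors, occupancy of
   the viewing area divided into 8 sectors (vertical strips numbered left
   to right, or 45° wedges), an angular rose of track headings, and a
   `max_k |f_k − 1/8|` uniformity statistic with its 3σ multinomial bound —
   the machinery needed to detect phototaxis-style directional bias.

A built-in **simulator** generates synthetic videos with exact ground-truth
trajectories (persistent random walks with per-strain speeds, optional
aggregates and directional light bias, reflective boundaries, Gaussian-blob
rendering with sensor noise), so every stage of the pipeline is validated
against known truth. Speed presets for the wild-type strain cc124,
twelve motility mutants, and *C. moewusii* are included.

## Worked example

```python
import chlamytrack as ct

scenario = ct.SimScenario(
    n_cells=30, n_frames=50,
    field_width_px=512, field_height_px=512,
    subpopulations=[ct.strain_preset("cc124")],   # wild type, 40.0 ± 4.5 µm/s
    min_separation_px=40, noise_sd=20.0, seed=1,
)
result = ct.run_pipeline(scenario=scenario, one_point_per_track=True)
print(result.summary.summary())
print(f"bias statistic: {result.bias.statistic:.3f} "
      f"(3-sigma threshold {result.bias.threshold:.3f})")
```

prints

```
Population speed summary (1 video(s), 38 tracks)
  mean of per-video means: 39.7 um/s
  standard error:          undefined (1 video)
  histogram (um/s bin: fraction):
          [0, 1): 0.000
         [1, 11): 0.000
        [11, 21): 0.000
        [21, 31): 0.000
        [31, 41): 0.684
        [41, 51): 0.316
        ...
bias statistic: 0.099 (3-sigma threshold 0.161)
```

The recovered population mean (39.7 µm/s) matches the preset strain mean
(40.0 µm/s) to within a percent; the histogram shows a single mode
straddling the mean; and the sector-occupancy statistic sits below its 3σ
bound — no directional bias, as expected for an unbiased simulation. (38
tracks from 30 cells: fast swimmers that cross paths can briefly lose their
identity, splitting a trajectory into fragments; fragments are still
correct speed samples.)

The same analysis runs on real recordings from the command line:

```bash
chlamytrack analyze video.tif --pixel-size 0.65 --duration 30 \
    --radius 5 --threshold 50 --out-dir results/
```

which writes the three tracking tables (`spots_in_tracks.csv`,
`track_statistics.csv`, `links_in_tracks.csv` — TrackMate-compatible column
names, positions in µm), the merged tab-delimited direction-vector table, a
JSON summary, a run manifest, and optional PNG figures (track heat map,
speed histogram, rose plot). `chlamytrack simulate` renders synthetic
videos from a TOML scenario; `chlamytrack rose` recomputes sector occupancy
from exported tables.

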