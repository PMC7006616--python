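"""End-to-end orchestration: stack or scenario in, tables and summaries out.

``run_pipeline`` composes the full workflow — (simulate) → detect → link →
track statistics → direction analysis → CSV export — deterministically:
identical inputs (including the scenario seed) reproduce identical output
bytes. A run manifest (configuration hash, package and library versions,
seed) is written alongside the outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
import os
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .detect import DetectionConfig, Spot, detect_stack
from .direction import (BiasResult, SectorOccupancy, bias_statistic,
                        direction_vectors, track_sector_occupancy)
from .errors import ValidationError
from .link import LinkingConfig, Track, build_tracks, close_gaps, default_gate_um, link_frames
from .simulate import GroundTruth, SimScenario, simulate_population
from .stack import ImageStack
from .tables import merge_tables, tables_from_tracks, write_merged, write_tables
from .trackstats import (DEFAULT_BIN_EDGES_UM_S, Calibration, PopulationSummary,
                         population_summary, track_speed)

__all__ = ["PipelineResult", "run_pipeline", "track_stack", "detection_for_scenario"]


def detection_for_scenario(scenario: SimScenario) -> DetectionConfig:
    """Detector settings matched to a simulated scenario.

    The expected radius equals the rendered blob radius; the quality
    threshold is 10% of the blob amplitude (the matched-scale LoG peak of a
    Gaussian blob is about half its amplitude, so this sits well below true
    peaks and well above background noise at the default noise levels).
    """
    return DetectionConfig(
        expected_radius_um=scenario.cell_radius_px * scenario.pixel_size_um,
        quality_threshold=0.1 * scenario.cell_intensity,
        invert_intensity=scenario.invert,
    )


def track_stack(
    stack: ImageStack,
    detection: Optional[DetectionConfig] = None,
    linking: Optional[LinkingConfig] = None,
) -> tuple[list[list[Spot]], list[Track]]:
    """Detect and link a stack; returns (spots per frame, tracks)."""
    if stack.n_frames < 2:
        raise ValidationError("tracking requires >= 2 frames")
    detection = detection or DetectionConfig()
    if linking is None:
        linking = LinkingConfig(max_link_distance_um=default_gate_um(stack.frame_interval_s))
    spots_by_frame = detect_stack(stack, detection)
    links = link_frames(spots_by_frame, linking, stack.pixel_size_um)
    tracks = build_tracks(links, spots_by_frame)
    if linking.max_gap_frames > 0:
        tracks = close_gaps(tracks, linking, stack.pixel_size_um)
    return spots_by_frame, tracks


@dataclass(frozen=True)
class PipelineResult:
    """Everything one pipeline run produced."""

    stack: ImageStack
    truth: Optional[GroundTruth]
    spots_by_frame: list
    tracks: list
    stats: list
    summary: PopulationSummary
    occupancy: SectorOccupancy
    bias: BiasResult
    vectors: list
    spots_table: pd.DataFrame
    tracks_table: pd.DataFrame
    links_table: pd.DataFrame
    merged_table: pd.DataFrame
    manifest: dict


def _manifest(config: dict, seed: Optional[int]) -> dict:
    canon = json.dumps(config, sort_keys=True, default=str)
    return {
        "config": config,
        "config_sha256": hashlib.sha256(canon.encode()).hexdigest(),
        "seed": seed,
        "versions": {
            "chlamytrack": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }


def run_pipeline(
    stack: Optional[ImageStack] = None,
    scenario: Optional[SimScenario] = None,
    out_dir: Optional[str | os.PathLike] = None,
    detection: Optional[DetectionConfig] = None,
    linking: Optional[LinkingConfig] = None,
    bin_edges_um_s: Sequence[float] = DEFAULT_BIN_EDGES_UM_S,
    min_spots: int = 3,
    n_sectors: int = 8,
    sector_mode: str = "strips",
    one_point_per_track: bool = False,
    make_plots: bool = False,
) -> PipelineResult:
    """Run the full workflow on a stack or on a simulated scenario.

    Exactly one of ``stack``/``scenario`` must be given. With ``out_dir``
    set, writes the three CSV tables, the merged tab-delimited table,
    ``summary.json`` and ``manifest.json`` (plus PNG figures with
    ``make_plots=True``).
    """
    if (stack is None) == (scenario is None):
        raise ValidationError("provide exactly one of stack or scenario")
    truth = None
    if scenario is not None:
        stack, truth = simulate_population(scenario)
        if detection is None:
            detection = detection_for_scenario(scenario)
    detection = detection or DetectionConfig()
    if linking is None:
        linking = LinkingConfig(max_link_distance_um=default_gate_um(stack.frame_interval_s))

    spots_by_frame, tracks = track_stack(stack, detection, linking)
    cal = Calibration.from_interval(stack.pixel_size_um, stack.frame_interval_s,
                                    stack.n_frames)
    stats = [track_speed(t, cal) for t in tracks]
    summary = population_summary([stats], bin_edges_um_s, min_spots=min_spots)
    vectors = direction_vectors(tracks, cal)
    occupancy = track_sector_occupancy(tracks, (stack.width_px, stack.height_px),
                                       n_sectors=n_sectors, mode=sector_mode,
                                       one_point_per_track=one_point_per_track)
    bias = bias_statistic(occupancy)
    spots_df, tracks_df, links_df = tables_from_tracks(tracks, cal)
    merged = merge_tables(spots_df, tracks_df, links_df)

    config = {
        "detection": dataclasses.asdict(detection),
        "linking": dataclasses.asdict(linking),
        "bin_edges_um_s": list(map(float, bin_edges_um_s)),
        "min_spots": min_spots,
        "n_sectors": n_sectors,
        "sector_mode": sector_mode,
        "one_point_per_track": one_point_per_track,
        "scenario": dataclasses.asdict(scenario) if scenario is not None else None,
        "calibration": dataclasses.asdict(cal),
    }
    manifest = _manifest(config, scenario.seed if scenario is not None else None)

    result = PipelineResult(
        stack=stack, truth=truth, spots_by_frame=spots_by_frame, tracks=tracks,
        stats=stats, summary=summary, occupancy=occupancy, bias=bias,
        vectors=vectors, spots_table=spots_df, tracks_table=tracks_df,
        links_table=links_df, merged_table=merged, manifest=manifest,
    )
    if out_dir is not None:
        _write_outputs(result, out_dir, make_plots)
    return result


def _json_default(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    raise TypeError(f"not JSON serializable: {type(o)}")


def _write_outputs(result: PipelineResult, out_dir: str | os.PathLike, make_plots: bool) -> None:
    out_dir = os.fspath(out_dir)
    os.makedirs(out_dir, exist_ok=True)
    write_tables(result.spots_table, result.tracks_table, result.links_table, out_dir)
    write_merged(result.merged_table, os.path.join(out_dir, "merged_tracks.tsv"))
    s = result.summary
    summary_json = {
        "n_videos": s.n_videos,
        "n_tracks": s.n_tracks,
        "mean_um_s": s.mean_um_s,
        "se_um_s": None if math.isnan(s.se_um_s) else s.se_um_s,
        "bin_edges_um_s": list(s.bin_edges_um_s),
        "histogram_fractions": list(s.histogram_fractions),
        "sector_mode": result.occupancy.mode,
        "sector_fractions": list(result.occupancy.fractions),
        "sector_n_points": result.occupancy.n_points,
        "bias_statistic": result.bias.statistic,
        "bias_threshold_3sigma": result.bias.threshold,
        "uniform": result.bias.uniform,
    }
    with open(os.path.join(out_dir, "summary.json"), "w", encoding="utf-8", newline="\n") as fh:
        json.dump(summary_json, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")
    with open(os.path.join(out_dir, "manifest.json"), "w", encoding="utf-8", newline="\n") as fh:
        json.dump(result.manifest, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")
    if make_plots:
        from .plots import save_rose, save_speed_histogram, save_track_heatmap

        field = (result.stack.width_px, result.stack.height_px)
        save_track_heatmap(result.tracks, field, os.path.join(out_dir, "tracks_heatmap.png"))
        save_speed_histogram(result.summary, os.path.join(out_dir, "speed_histogram.png"))
        save_rose(result.occupancy, os.path.join(out_dir, "rose.png"))
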