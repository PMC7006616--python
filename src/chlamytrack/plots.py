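"""Optional figure outputs: track-overlay heat map, speed histogram, rose plot."""

from __future__ import annotations

import os
from typing import Sequence

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from .direction import SectorOccupancy
from .link import Track
from .trackstats import PopulationSummary

__all__ = ["save_track_heatmap", "save_speed_histogram", "save_rose"]


def save_track_heatmap(
    tracks: Sequence[Track],
    field: tuple[int, int],
    path: str | os.PathLike,
) -> None:
    """2-D histogram of all track coordinates over the field."""
    w, h = field
    xs = [s.x_px for t in tracks for s in t.spots]
    ys = [s.y_px for t in tracks for s in t.spots]
    fig, ax = plt.subplots(figsize=(5, 5 * h / max(w, 1)))
    if xs:
        ax.hist2d(xs, ys, bins=[min(w, 128), min(h, 128)],
                  range=[[0, w], [0, h]], cmap="inferno")
    ax.set_xlim(0, w)
    ax.set_ylim(h, 0)  # image convention: y down
    ax.set_xlabel("x (px)")
    ax.set_ylabel("y (px)")
    ax.set_title(f"Track coordinates ({len(tracks)} tracks)")
    fig.savefig(path, dpi=120)
    plt.close(fig)


def save_speed_histogram(summary: PopulationSummary, path: str | os.PathLike) -> None:
    edges = np.asarray(summary.bin_edges_um_s)
    frac = np.asarray(summary.histogram_fractions)
    centers = list((edges[:-1] + edges[1:]) / 2.0) + [edges[-1] + (edges[-1] - edges[-2]) / 2.0]
    widths = list(np.diff(edges)) + [edges[-1] - edges[-2]]
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.bar(centers, frac, width=np.asarray(widths) * 0.9, color="#3b7", edgecolor="k")
    ax.set_xlabel("mean track speed (µm/s)")
    ax.set_ylabel("fraction of tracks")
    ax.set_title(f"n = {summary.n_tracks} tracks; mean {summary.mean_um_s:.1f} µm/s")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def save_rose(occupancy: SectorOccupancy, path: str | os.PathLike) -> None:
    """Bar chart (strips) or polar rose (wedges) of sector occupancy."""
    k = occupancy.n_sectors
    frac = np.asarray(occupancy.fractions)
    if occupancy.mode == "strips":
        fig, ax = plt.subplots(figsize=(6, 4))
        ax.bar(np.arange(1, k + 1), frac, color="#47a", edgecolor="k")
        ax.axhline(1.0 / k, ls="--", c="gray", label="uniform")
        ax.set_xlabel("section (left to right)")
        ax.set_ylabel("fraction of coordinates")
        ax.legend()
    else:
        fig = plt.figure(figsize=(5, 5))
        ax = fig.add_subplot(projection="polar")
        # wedge 1 centered on -x, clockwise on screen
        theta = np.pi + np.arange(k) * 2 * np.pi / k
        ax.bar(theta, frac, width=2 * np.pi / k * 0.95, color="#47a", edgecolor="k")
    ax.set_title(f"Sector occupancy ({occupancy.mode}, n = {occupancy.n_points})")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
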