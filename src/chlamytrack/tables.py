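"""The three tracking export tables and their merge.

The pipeline exports the same three CSV tables a TrackMate-based workflow
produces — "Spots in tracks statistics", "Track statistics" and "Links in
tracks statistics" — with compatible column names, coordinates in µm and
times in seconds (FRAME is 0-based). ``merge_tables`` reproduces the
downstream merge that joins the three tables into one tab-delimited row per
track augmented with its direction vector (DX_UM, DY_UM, ANGLE_RAD).
"""

from __future__ import annotations

import math
import os
from typing import Sequence

import pandas as pd

from .errors import IntegrityError
from .link import Track
from .trackstats import Calibration, track_speed

__all__ = [
    "SPOTS_COLUMNS",
    "TRACKS_COLUMNS",
    "LINKS_COLUMNS",
    "spots_in_tracks_table",
    "track_statistics_table",
    "links_in_tracks_table",
    "write_tables",
    "read_tables",
    "merge_tables",
    "write_merged",
]

SPOTS_COLUMNS = ("TRACK_ID", "SPOT_ID", "FRAME", "POSITION_X", "POSITION_Y",
                 "POSITION_T", "RADIUS", "QUALITY")
TRACKS_COLUMNS = ("TRACK_ID", "NUMBER_SPOTS", "TRACK_DURATION",
                  "TRACK_DISPLACEMENT", "TRACK_MEAN_SPEED", "TRACK_MAX_SPEED")
LINKS_COLUMNS = ("TRACK_ID", "SPOT_SOURCE_ID", "SPOT_TARGET_ID", "LINK_COST", "SPEED")

SPOTS_FILE = "spots_in_tracks.csv"
TRACKS_FILE = "track_statistics.csv"
LINKS_FILE = "links_in_tracks.csv"


def spots_in_tracks_table(tracks: Sequence[Track], cal: Calibration) -> pd.DataFrame:
    """Per-spot table: positions in µm, POSITION_T in seconds, FRAME 0-based."""
    rows = []
    for t in tracks:
        for s in t.spots:
            rows.append((t.track_id, s.spot_id, s.frame,
                         s.x_px * cal.pixel_size_um, s.y_px * cal.pixel_size_um,
                         s.frame * cal.frame_interval_s,
                         s.radius_px * cal.pixel_size_um, s.quality))
    return pd.DataFrame(rows, columns=list(SPOTS_COLUMNS))


def track_statistics_table(tracks: Sequence[Track], cal: Calibration) -> pd.DataFrame:
    """Per-track table built from :func:`~chlamytrack.trackstats.track_speed`."""
    rows = []
    for t in tracks:
        st = track_speed(t, cal)
        rows.append((t.track_id, st.n_spots, st.duration_s, st.net_displacement_um,
                     st.mean_speed_um_s, st.max_link_speed_um_s))
    return pd.DataFrame(rows, columns=list(TRACKS_COLUMNS))


def links_in_tracks_table(tracks: Sequence[Track], cal: Calibration) -> pd.DataFrame:
    """Per-link table; LINK_COST is the squared displacement in µm²."""
    rows = []
    dt = cal.frame_interval_s
    for t in tracks:
        for a, b in zip(t.spots, t.spots[1:]):
            d_um = math.hypot(b.x_px - a.x_px, b.y_px - a.y_px) * cal.pixel_size_um
            rows.append((t.track_id, a.spot_id, b.spot_id, d_um ** 2,
                         d_um / ((b.frame - a.frame) * dt)))
    return pd.DataFrame(rows, columns=list(LINKS_COLUMNS))


def _write_csv(df: pd.DataFrame, path: str, sep: str = ",") -> None:
    df.to_csv(path, sep=sep, index=False, float_format="%.6g", lineterminator="\n",
              encoding="utf-8")


def write_tables(
    spots: pd.DataFrame,
    tracks: pd.DataFrame,
    links: pd.DataFrame,
    out_dir: str | os.PathLike,
) -> dict[str, str]:
    """Write the three CSV tables (UTF-8, LF, 6 significant digits).

    Referential consistency (every spots/links TRACK_ID exists in the tracks
    table; every link endpoint exists in the spots table) is verified before
    any file is written.
    """
    _check_integrity(spots, tracks, links)
    out_dir = os.fspath(out_dir)
    os.makedirs(out_dir, exist_ok=True)
    paths = {
        "spots": os.path.join(out_dir, SPOTS_FILE),
        "tracks": os.path.join(out_dir, TRACKS_FILE),
        "links": os.path.join(out_dir, LINKS_FILE),
    }
    _write_csv(spots, paths["spots"])
    _write_csv(tracks, paths["tracks"])
    _write_csv(links, paths["links"])
    return paths


def read_tables(out_dir: str | os.PathLike) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    out_dir = os.fspath(out_dir)
    spots = pd.read_csv(os.path.join(out_dir, SPOTS_FILE))
    tracks = pd.read_csv(os.path.join(out_dir, TRACKS_FILE))
    links = pd.read_csv(os.path.join(out_dir, LINKS_FILE))
    return spots, tracks, links


def _check_integrity(spots: pd.DataFrame, tracks: pd.DataFrame, links: pd.DataFrame) -> None:
    track_ids = set(tracks["TRACK_ID"].tolist())
    orphan = sorted(set(spots["TRACK_ID"]) - track_ids)
    if orphan:
        raise IntegrityError(f"spots table references unknown TRACK_ID(s): {orphan}")
    orphan = sorted(set(links["TRACK_ID"]) - track_ids)
    if orphan:
        raise IntegrityError(f"links table references unknown TRACK_ID(s): {orphan}")
    spot_ids = set(spots["SPOT_ID"].tolist())
    for col in ("SPOT_SOURCE_ID", "SPOT_TARGET_ID"):
        orphan = sorted(set(links[col]) - spot_ids)
        if orphan:
            raise IntegrityError(f"links table {col} references unknown spot(s): {orphan}")


def merge_tables(
    spots: pd.DataFrame,
    tracks: pd.DataFrame,
    links: pd.DataFrame,
) -> pd.DataFrame:
    """One row per track: the tracks table joined with its direction vector.

    DX_UM/DY_UM are last-spot minus first-spot positions (already in µm in
    the spots table); ANGLE_RAD is their atan2 heading (NaN for zero net
    displacement). Only tracks with >= 2 spots appear.
    """
    _check_integrity(spots, tracks, links)
    vec_rows = []
    for tid, grp in spots.sort_values(["TRACK_ID", "FRAME"]).groupby("TRACK_ID"):
        if len(grp) < 2:
            continue
        dx = float(grp["POSITION_X"].iloc[-1] - grp["POSITION_X"].iloc[0])
        dy = float(grp["POSITION_Y"].iloc[-1] - grp["POSITION_Y"].iloc[0])
        mag = math.hypot(dx, dy)
        vec_rows.append((tid, dx, dy, math.atan2(dy, dx) if mag > 0 else float("nan")))
    vectors = pd.DataFrame(vec_rows, columns=["TRACK_ID", "DX_UM", "DY_UM", "ANGLE_RAD"])
    n_links = links.groupby("TRACK_ID").size().rename("NUMBER_LINKS").reset_index()
    merged = tracks.merge(vectors, on="TRACK_ID", how="inner")
    merged = merged.merge(n_links, on="TRACK_ID", how="left")
    merged["NUMBER_LINKS"] = merged["NUMBER_LINKS"].fillna(0).astype(int)
    return merged.sort_values("TRACK_ID").reset_index(drop=True)


def write_merged(merged: pd.DataFrame, path: str | os.PathLike) -> None:
    """Write the merged table as tab-delimited text."""
    _write_csv(merged, os.fspath(path), sep="\t")


def tables_from_tracks(
    tracks: Sequence[Track], cal: Calibration
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Convenience: all three export tables from in-memory tracks."""
    return (
        spots_in_tracks_table(tracks, cal),
        track_statistics_table(tracks, cal),
        links_in_tracks_table(tracks, cal),
    )
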