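"""Uterine-zone sperm localization and track-velocity statistics.

The uterus is modelled as the straight segment from the vulva to the
spermatheca, divided into thirds: zone 1 is the vulval third, zone 2 the
central third, zone 3 the spermathecal third.  Sperm are projected onto the
axis; boundaries are half-open ([0,1/3), [1/3,2/3), [2/3,1]), so a sperm at
exactly 1/3 falls in zone 2.  Projections outside [0,1] are clamped with a
warning.

Track speed is total path length divided by elapsed time (the tracking
convention); net displacement over time is offered separately as a
progressivity metric.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "UterusScene",
    "Track",
    "assign_zones",
    "track_speed",
    "net_progressivity",
    "read_tracks",
    "tracks_from_frame",
    "gonad_arm_velocity",
]


@dataclass
class UterusScene:
    vulva_point: tuple[float, float]
    spermatheca_point: tuple[float, float]
    sperm_points: list[tuple[float, float]] = field(default_factory=list)
    zone_boundaries: tuple[float, float] = (1.0 / 3.0, 2.0 / 3.0)

    def __post_init__(self) -> None:
        if np.allclose(self.vulva_point, self.spermatheca_point):
            raise ValueError("vulva and spermatheca must be distinct points")
        b1, b2 = self.zone_boundaries
        if not 0 < b1 < b2 < 1:
            raise ValueError("zone boundaries must satisfy 0 < b1 < b2 < 1")


@dataclass
class Track:
    """One sperm trajectory: samples are (t_seconds, row, col) with strictly
    increasing time; a speed needs at least two samples."""

    track_id: int
    samples: np.ndarray

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2 or self.samples.shape[1] != 3:
            raise ValueError("samples must be an (n, 3) array of (t, row, col)")
        t = self.samples[:, 0]
        if np.any(np.diff(t) <= 0):
            raise ValueError("timestamps must be strictly increasing")


def axis_fraction(scene: UterusScene, points: np.ndarray) -> np.ndarray:
    """Project points onto the vulva->spermatheca axis as fractions in [0,1],
    clamping (with a warning) anything projecting outside."""
    v = np.asarray(scene.vulva_point, dtype=float)
    s = np.asarray(scene.spermatheca_point, dtype=float)
    axis = s - v
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    f = (pts - v) @ axis / float(axis @ axis)
    if np.any((f < 0) | (f > 1)):
        warnings.warn("sperm project outside the vulva-spermatheca axis; clamped",
                      stacklevel=2)
        f = np.clip(f, 0.0, 1.0)
    return f


def assign_zones(scene: UterusScene) -> tuple[np.ndarray, dict[int, float]]:
    """Zone (1/2/3) per sperm plus the per-zone fractions (summing to 1)."""
    if not scene.sperm_points:
        raise ValueError("scene has no sperm")
    f = axis_fraction(scene, np.asarray(scene.sperm_points))
    b1, b2 = scene.zone_boundaries
    zones = np.where(f < b1, 1, np.where(f < b2, 2, 3))
    n = len(zones)
    fractions = {z: float(np.sum(zones == z)) / n for z in (1, 2, 3)}
    return zones, fractions


def track_speed(track: Track) -> float:
    """Average speed: total path length / (t_last - t_first)."""
    if len(track.samples) < 2:
        raise ValueError("a speed needs at least two samples")
    xy = track.samples[:, 1:]
    path = float(np.linalg.norm(np.diff(xy, axis=0), axis=1).sum())
    duration = float(track.samples[-1, 0] - track.samples[0, 0])
    return path / duration


def net_progressivity(track: Track) -> float:
    """Secondary metric: net displacement / elapsed time (<= track_speed)."""
    if len(track.samples) < 2:
        raise ValueError("a speed needs at least two samples")
    net = float(np.linalg.norm(track.samples[-1, 1:] - track.samples[0, 1:]))
    return net / float(track.samples[-1, 0] - track.samples[0, 0])


def read_tracks(path, frame_interval_s: float = 30.0) -> list[Track]:
    """Ingest a track CSV with columns ``track, frame, x, y`` (or
    ``row, col``), optionally ``t``/``t_seconds``; missing times come from
    frame x interval (default 30 s between frames)."""
    return tracks_from_frame(pd.read_csv(path), frame_interval_s)


def tracks_from_frame(frame: pd.DataFrame, frame_interval_s: float = 30.0) -> list[Track]:
    cols = {c.lower(): c for c in frame.columns}
    tcol = cols.get("t_seconds") or cols.get("t")
    if "row" in cols and "col" in cols:
        rc, cc = cols["row"], cols["col"]
    elif "x" in cols and "y" in cols:
        rc, cc = cols["y"], cols["x"]      # x is the column axis
    else:
        raise ValueError("track table needs row/col or x/y columns")
    if "track" not in cols:
        raise ValueError("track table needs a 'track' column")
    tracks = []
    for tid, grp in frame.groupby(cols["track"], sort=True):
        grp = grp.sort_values(cols["frame"]) if "frame" in cols else grp
        if tcol is not None:
            t = grp[tcol].to_numpy(dtype=float)
        else:
            t = grp[cols["frame"]].to_numpy(dtype=float) * frame_interval_s
        samples = np.column_stack([t, grp[rc].to_numpy(float), grp[cc].to_numpy(float)])
        tracks.append(Track(track_id=int(tid), samples=samples))
    return tracks


def gonad_arm_velocity(track_table: pd.DataFrame, zone_filter: int | None = 2) -> pd.DataFrame:
    """Mean per-track speed per gonad arm, over zone-2 tracks by default.

    ``track_table`` needs columns ``arm``, ``zone``, ``speed`` (one row per
    track).  Arms with no qualifying track are reported with a missing (nan)
    velocity, never zero.
    """
    for col in ("arm", "zone", "speed"):
        if col not in track_table.columns:
            raise ValueError(f"track table needs a {col!r} column")
    rows = []
    for arm, grp in track_table.groupby("arm", sort=True):
        sel = grp if zone_filter is None else grp[grp["zone"] == zone_filter]
        rows.append({
            "arm": arm,
            "mean_speed": float(sel["speed"].mean()) if len(sel) else float("nan"),
            "n_tracks": int(len(sel)),
        })
    return pd.DataFrame(rows)
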