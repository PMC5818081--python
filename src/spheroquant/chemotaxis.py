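"""Chemotaxis track statistics.

Per-track statistics of time-lapse cell migration (velocity, Euclidean and
accumulated distance, net-displacement direction) and population-level
directionality: the percentage of cells whose net displacement points toward
each reservoir of a two-reservoir chemotaxis slide, and the Rayleigh test of
circular uniformity on per-cell net-displacement angles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .errors import FormatError, ParameterError

__all__ = [
    "Track",
    "TrackSet",
    "TrackSummary",
    "ChemotaxisReport",
    "read_tracks",
    "write_tracks",
    "summarize_track",
    "net_displacement_summary",
    "rayleigh_test",
]

#: image axis pointing toward the "right reservoir" -> unit vector (x, y)
_AXES = {
    "+x": (1.0, 0.0),
    "-x": (-1.0, 0.0),
    "+y": (0.0, 1.0),
    "-y": (0.0, -1.0),
}


@dataclass(frozen=True)
class Track:
    """One cell's trajectory: time stamps (min) and positions (µm)."""

    track_id: Union[int, str]
    t_min: np.ndarray
    x_um: np.ndarray
    y_um: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.t_min, dtype=float)
        x = np.asarray(self.x_um, dtype=float)
        y = np.asarray(self.y_um, dtype=float)
        if not (t.shape == x.shape == y.shape) or t.ndim != 1:
            raise ParameterError("t_min, x_um, y_um must be equal-length 1-D")
        if t.size < 2:
            raise ParameterError("a track needs at least 2 samples")
        if not np.all(np.diff(t) > 0):
            raise ParameterError("time stamps must be strictly increasing")
        object.__setattr__(self, "t_min", t)
        object.__setattr__(self, "x_um", x)
        object.__setattr__(self, "y_um", y)

    @property
    def n_samples(self) -> int:
        return self.t_min.size


@dataclass(frozen=True)
class TrackSet:
    """A collection of tracks plus the slide orientation convention."""

    tracks: tuple[Track, ...]
    axis_convention: str = "+x"

    def __post_init__(self) -> None:
        tracks = tuple(self.tracks)
        if not tracks:
            raise ParameterError("a TrackSet needs at least one track")
        ids = [t.track_id for t in tracks]
        if len(set(ids)) != len(ids):
            raise ParameterError("track_ids must be unique")
        if self.axis_convention not in _AXES:
            raise ParameterError(
                f"axis_convention must be one of {sorted(_AXES)}"
            )
        object.__setattr__(self, "tracks", tracks)

    def __len__(self) -> int:
        return len(self.tracks)


@dataclass(frozen=True)
class TrackSummary:
    velocity_um_per_min: float
    euclidean_um: float
    accumulated_um: float
    net_vector_um: tuple[float, float]
    direction_rad: float


@dataclass(frozen=True)
class ChemotaxisReport:
    """Population directionality: left/right percentages + Rayleigh test."""

    pct_toward_right: float
    pct_toward_left: float
    pct_zero: float
    n_tracks: int
    rayleigh_R: float
    rayleigh_z: float
    rayleigh_p: float


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_tracks(
    path: Union[str, Path],
    pixel_size_um: Optional[float] = None,
    interval_min: Optional[float] = None,
    axis_convention: str = "+x",
) -> TrackSet:
    """Read a track table (CSV) into a TrackSet, converting to µm/min.

    The table needs ``track_id`` and ``frame`` columns plus positions either
    already calibrated (``x_um``, ``y_um``) or in pixels (``x``, ``y``, with
    ``pixel_size_um`` required).  Time comes from a ``t_min`` column when
    present, otherwise from ``frame * interval_min``.  Rows are sorted by
    frame within each track; duplicate (track, frame) rows are an error.
    """
    df = pd.read_csv(path)
    for col in ("track_id", "frame"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")

    if {"x_um", "y_um"} <= set(df.columns):
        x = df["x_um"].to_numpy(float)
        y = df["y_um"].to_numpy(float)
    elif {"x", "y"} <= set(df.columns):
        if pixel_size_um is None:
            raise FormatError(
                f"{path}: pixel-unit columns x,y need pixel_size_um"
            )
        x = df["x"].to_numpy(float) * pixel_size_um
        y = df["y"].to_numpy(float) * pixel_size_um
    else:
        raise FormatError(f"{path}: missing position columns (x_um,y_um or x,y)")

    dup = df.duplicated(subset=["track_id", "frame"])
    if dup.any():
        row = int(np.flatnonzero(dup.to_numpy())[0])
        raise FormatError(f"{path}: duplicate (track_id, frame) at data row {row}")

    if "t_min" in df.columns:
        t = df["t_min"].to_numpy(float)
    else:
        if interval_min is None:
            raise FormatError(f"{path}: no t_min column and no interval_min given")
        t = df["frame"].to_numpy(float) * interval_min

    work = pd.DataFrame(
        {"track_id": df["track_id"], "frame": df["frame"], "t": t, "x": x, "y": y}
    )
    tracks = []
    for tid, grp in work.groupby("track_id", sort=True):
        grp = grp.sort_values("frame")
        tracks.append(
            Track(
                track_id=tid,
                t_min=grp["t"].to_numpy(),
                x_um=grp["x"].to_numpy(),
                y_um=grp["y"].to_numpy(),
            )
        )
    return TrackSet(tracks=tuple(tracks), axis_convention=axis_convention)


def write_tracks(track_set: TrackSet, path: Union[str, Path]) -> None:
    """Write a TrackSet as CSV with header track_id,frame,t_min,x_um,y_um."""
    rows = []
    for tr in track_set.tracks:
        for frame, (t, x, y) in enumerate(zip(tr.t_min, tr.x_um, tr.y_um)):
            rows.append((tr.track_id, frame, t, x, y))
    pd.DataFrame(
        rows, columns=["track_id", "frame", "t_min", "x_um", "y_um"]
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Statistics
# ---------------------------------------------------------------------------

def summarize_track(track: Track, velocity: str = "accumulated") -> TrackSummary:
    """Velocity, Euclidean/accumulated distance and net direction of a track.

    ``accumulated`` is the total path length (sum of step lengths),
    ``euclidean`` the straight-line start-to-end displacement.  Velocity is
    accumulated path length over elapsed time — the convention of the
    migration-tracking ecosystem — or, with ``velocity="euclidean"``, the net
    displacement rate.
    """
    if velocity not in ("accumulated", "euclidean"):
        raise ParameterError("velocity must be 'accumulated' or 'euclidean'")
    dx = np.diff(track.x_um)
    dy = np.diff(track.y_um)
    accumulated = float(np.hypot(dx, dy).sum())
    net = (
        float(track.x_um[-1] - track.x_um[0]),
        float(track.y_um[-1] - track.y_um[0]),
    )
    euclidean = float(math.hypot(*net))
    elapsed = float(track.t_min[-1] - track.t_min[0])
    if elapsed <= 0:
        raise ParameterError("track has zero elapsed time")
    dist = accumulated if velocity == "accumulated" else euclidean
    return TrackSummary(
        velocity_um_per_min=dist / elapsed,
        euclidean_um=euclidean,
        accumulated_um=accumulated,
        net_vector_um=net,
        direction_rad=math.atan2(net[1], net[0]),
    )


def rayleigh_test(directions: Sequence[float]) -> tuple[float, float, float]:
    """Rayleigh test of circular uniformity.

    Returns ``(R, Z, p)`` with R the mean resultant length
    ``|sum_k exp(i theta_k)| / n``, Z = n R², and p from the standard series
    approximation with first- and second-order small-sample corrections:

        p ≈ exp(-Z) [1 + (2Z - Z²)/(4n) - (24Z - 132Z² + 76Z³ - 9Z⁴)/(288n²)]

    clamped to (0, 1].  Small p rejects the null of uniform directions.
    """
    theta = np.asarray(directions, dtype=float)
    n = theta.size
    if n < 3:
        raise ParameterError("rayleigh_test needs at least 3 angles")
    c = np.cos(theta).sum()
    s = np.sin(theta).sum()
    R = float(np.hypot(c, s) / n)
    Z = n * R * R
    p = math.exp(-Z) * (
        1.0
        + (2.0 * Z - Z * Z) / (4.0 * n)
        - (24.0 * Z - 132.0 * Z**2 + 76.0 * Z**3 - 9.0 * Z**4) / (288.0 * n * n)
    )
    p = min(1.0, max(p, np.finfo(float).tiny))
    return R, float(Z), float(p)


def net_displacement_summary(
    track_set: TrackSet, axis: Optional[str] = None
) -> ChemotaxisReport:
    """Population directionality of a track set.

    A track counts "toward right" when the signed component of its net
    displacement along the reservoir axis is positive, "toward left" when
    negative; exact zeros form a third class and contribute to neither side.
    The Rayleigh test runs on the net-displacement angles of all tracks with
    non-zero net displacement (one angle per cell); its fields are NaN when
    fewer than 3 such tracks exist.
    """
    axis = axis or track_set.axis_convention
    if axis not in _AXES:
        raise ParameterError(f"axis must be one of {sorted(_AXES)}")
    ux, uy = _AXES[axis]

    summaries = [summarize_track(t) for t in track_set.tracks]
    n = len(summaries)
    comps = np.array(
        [s.net_vector_um[0] * ux + s.net_vector_um[1] * uy for s in summaries]
    )
    nonzero_dirs = [
        s.direction_rad for s in summaries if s.euclidean_um > 0.0
    ]
    n_right = int((comps > 0).sum())
    n_left = int((comps < 0).sum())
    if len(nonzero_dirs) >= 3:
        R, Z, p = rayleigh_test(nonzero_dirs)
    else:
        R = Z = p = math.nan
    return ChemotaxisReport(
        pct_toward_right=100.0 * n_right / n,
        pct_toward_left=100.0 * n_left / n,
        pct_zero=100.0 * (n - n_right - n_left) / n,
        n_tracks=n,
        rayleigh_R=R,
        rayleigh_z=Z,
        rayleigh_p=p,
    )
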