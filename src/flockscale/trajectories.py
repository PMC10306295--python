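"""Track tables, Gaussian trajectory smoothing, and velocity estimation.

Raw cell tracks from time-lapse imaging are erratic, so positions are
smoothed over time with a fixed 9-point Gaussian kernel before velocities
are taken by centered finite differences:

    xbar_i(t) = sum_{k=-4..4} phi_k x_i(t - k dt),   phi_k = C exp(-k^2/4)
    vbar_i(t) = (xbar_i(t + dt) - xbar_i(t - dt)) / (2 dt)

with C chosen so the weights sum to one.  Frames lacking a full 9-point
stencil are dropped rather than renormalized, so the kernel is applied
exactly as written; likewise the difference endpoints are dropped.  Unit
velocity vectors s_i = v_i/|v_i| and their angles theta_i in [0, 2pi)
(counterclockwise from +x) feed every downstream statistic; cells with
exactly zero velocity at a frame are excluded from that snapshot and
counted in an exclusion tally.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import TrackFormatError, TrackValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "TrackSet",
    "VelocitySnapshot",
    "SnapshotSeries",
    "smoothing_kernel",
    "read_tracks",
    "write_tracks",
    "gaussian_smooth",
    "estimate_velocities",
]

TWO_PI = 2.0 * np.pi

#: Half-width of the smoothing stencil (frames); the kernel spans 2*HALF+1 points.
KERNEL_HALF = 4


def smoothing_kernel() -> np.ndarray:
    """The 9-point Gaussian weights phi_k = C e^{-k^2/4}, k = -4..4, sum 1."""
    k = np.arange(-KERNEL_HALF, KERNEL_HALF + 1, dtype=float)
    phi = np.exp(-(k**2) / 4.0)
    return phi / phi.sum()


@dataclass(frozen=True)
class TrackSet:
    """Per-cell (frame, x, y) series with a fixed frame interval (minutes)."""

    frame: pd.DataFrame = field(repr=False)  # columns track_id, frame, x_um, y_um
    frame_interval: float = 10.0

    def __post_init__(self):
        if self.frame_interval <= 0:
            raise TrackValidationError("frame_interval must be positive")

    @classmethod
    def from_frame(cls, df: pd.DataFrame, frame_interval: float = 10.0) -> "TrackSet":
        required = ["track_id", "frame", "x_um", "y_um"]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise TrackFormatError(f"missing columns: {missing}")
        df = df.loc[:, required].copy()
        df["frame"] = df["frame"].astype(int)
        df[["x_um", "y_um"]] = df[["x_um", "y_um"]].astype(float)
        if not np.all(np.isfinite(df[["x_um", "y_um"]].to_numpy())):
            raise TrackValidationError("non-finite coordinates")
        dup = df.duplicated(["track_id", "frame"])
        if dup.any():
            bad = df.loc[dup, "track_id"].iloc[0]
            raise TrackValidationError(f"duplicate (track, frame) in track {bad!r}")
        df = df.sort_values(["track_id", "frame"], kind="stable").reset_index(drop=True)
        return cls(df, frame_interval)

    @property
    def track_ids(self) -> list:
        return list(dict.fromkeys(self.frame["track_id"]))

    @property
    def n_tracks(self) -> int:
        return self.frame["track_id"].nunique()

    def track(self, track_id) -> pd.DataFrame:
        return self.frame[self.frame["track_id"] == track_id]

    def __len__(self) -> int:
        return len(self.frame)


@dataclass(frozen=True)
class VelocitySnapshot:
    """One time point: positions, velocities, unit vectors, angles."""

    time: float  # minutes
    cell_ids: np.ndarray
    positions: np.ndarray  # (n, 2) um
    velocities: np.ndarray  # (n, 2) um/min
    unit_velocities: np.ndarray  # (n, 2)
    angles: np.ndarray  # (n,) in [0, 2pi)

    @property
    def n_cells(self) -> int:
        return len(self.angles)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "t_min": self.time,
                "cell_id": self.cell_ids,
                "x_um": self.positions[:, 0],
                "y_um": self.positions[:, 1],
                "vx_um_min": self.velocities[:, 0],
                "vy_um_min": self.velocities[:, 1],
                "theta_rad": self.angles,
            }
        )


@dataclass
class SnapshotSeries:
    """Time-ordered velocity snapshots plus the zero-velocity exclusion tally."""

    snapshots: list[VelocitySnapshot]
    n_zero_velocity_excluded: int = 0

    def __iter__(self):
        return iter(self.snapshots)

    def __len__(self):
        return len(self.snapshots)

    def __getitem__(self, i):
        return self.snapshots[i]

    def to_frame(self) -> pd.DataFrame:
        return pd.concat([s.to_frame() for s in self.snapshots], ignore_index=True)


_TRACKMATE_COLUMNS = {
    "track_id": ("track_id", "trackid"),
    "frame": ("frame",),
    "x_um": ("position_x", "x"),
    "y_um": ("position_y", "y"),
}


def read_tracks(
    path: str | Path, dialect: str = "simple_csv", frame_interval: float = 10.0
) -> TrackSet:
    """Read a track table.

    ``simple_csv``: header ``track_id,frame,x_um,y_um``.
    ``trackmate_export``: TrackMate spot export; columns TRACK_ID / FRAME /
    POSITION_X / POSITION_Y are resolved case-insensitively and the
    secondary descriptive header rows of newer exports are skipped.
    """
    path = Path(path)
    if dialect == "simple_csv":
        df = pd.read_csv(path)
        return TrackSet.from_frame(df, frame_interval)
    if dialect == "trackmate_export":
        raw = pd.read_csv(path, dtype=str)
        raw.columns = [c.strip().lower() for c in raw.columns]
        cols = {}
        for ours, candidates in _TRACKMATE_COLUMNS.items():
            for c in candidates:
                if c in raw.columns:
                    cols[ours] = c
                    break
            else:
                raise TrackFormatError(f"cannot resolve column for {ours!r} in {path}")
        df = raw[[cols[k] for k in _TRACKMATE_COLUMNS]].copy()
        df.columns = list(_TRACKMATE_COLUMNS)
        # TrackMate >= 7 writes 3 extra human-readable header rows; drop any
        # row whose frame is not numeric.
        numeric = pd.to_numeric(df["frame"], errors="coerce")
        df = df[numeric.notna()]
        df["frame"] = numeric[numeric.notna()].astype(float).astype(int)
        df["x_um"] = df["x_um"].astype(float)
        df["y_um"] = df["y_um"].astype(float)
        df = df[pd.to_numeric(df["track_id"], errors="coerce").notna()]
        df["track_id"] = pd.to_numeric(df["track_id"]).astype(int)
        return TrackSet.from_frame(df, frame_interval)
    raise ValueError(f"unknown dialect {dialect!r}")


def write_tracks(tracks: TrackSet, path: str | Path) -> None:
    tracks.frame.to_csv(path, index=False)


def _contiguous_runs(frames: np.ndarray) -> list[slice]:
    """Slices of maximal runs of consecutive frames (gaps break runs)."""
    breaks = np.flatnonzero(np.diff(frames) != 1)
    edges = np.concatenate([[0], breaks + 1, [len(frames)]])
    return [slice(a, b) for a, b in zip(edges[:-1], edges[1:])]


def gaussian_smooth(tracks: TrackSet) -> TrackSet:
    """Smooth every track with the 9-point Gaussian kernel.

    Only frames with a full stencil inside a contiguous run carry smoothed
    values; runs shorter than 9 frames produce nothing and are logged.
    Missing frames inside a track break it into independent runs, so the
    smoothing window never spans a gap.
    """
    phi = smoothing_kernel()
    out = []
    n_short = 0
    for tid, g in tracks.frame.groupby("track_id", sort=False):
        frames = g["frame"].to_numpy()
        xy = g[["x_um", "y_um"]].to_numpy()
        for run in _contiguous_runs(frames):
            f = frames[run]
            if len(f) < len(phi):
                n_short += 1
                continue
            # kernel uses x(t - k dt) for k=-4..4, i.e. correlation with
            # reversed offsets; phi is symmetric so convolve == correlate
            sx = np.convolve(xy[run, 0], phi, mode="valid")
            sy = np.convolve(xy[run, 1], phi, mode="valid")
            out.append(
                pd.DataFrame(
                    {
                        "track_id": tid,
                        "frame": f[KERNEL_HALF:-KERNEL_HALF],
                        "x_um": sx,
                        "y_um": sy,
                    }
                )
            )
    if n_short:
        logger.warning("gaussian_smooth: skipped %d run(s) shorter than 9 frames", n_short)
    if not out:
        df = pd.DataFrame(columns=["track_id", "frame", "x_um", "y_um"])
    else:
        df = pd.concat(out, ignore_index=True)
    return TrackSet(df, tracks.frame_interval)


def estimate_velocities(smoothed: TrackSet) -> SnapshotSeries:
    """Centered-difference velocities, unit vectors, and angles per frame.

    v(t) = (x(t+dt) - x(t-dt)) / (2 dt); run endpoints are dropped.  Cells
    with |v| = 0 are excluded from that snapshot (their direction is
    undefined) and tallied.
    """
    dt = smoothed.frame_interval
    rows = []
    n_zero = 0
    for tid, g in smoothed.frame.groupby("track_id", sort=False):
        frames = g["frame"].to_numpy()
        xy = g[["x_um", "y_um"]].to_numpy()
        for run in _contiguous_runs(frames):
            f = frames[run]
            if len(f) < 3:
                continue
            p = xy[run]
            v = (p[2:] - p[:-2]) / (2.0 * dt)
            rows.append((tid, f[1:-1], p[1:-1], v))
    by_frame: dict[int, list] = {}
    for tid, f, p, v in rows:
        for k in range(len(f)):
            by_frame.setdefault(int(f[k]), []).append((tid, p[k], v[k]))
    snapshots = []
    for fr in sorted(by_frame):
        entries = by_frame[fr]
        cell_ids = np.array([e[0] for e in entries])
        pos = np.array([e[1] for e in entries])
        vel = np.array([e[2] for e in entries])
        speed = np.linalg.norm(vel, axis=1)
        keep = speed > 0.0
        n_zero += int((~keep).sum())
        if not keep.any():
            continue
        vel = vel[keep]
        unit = vel / speed[keep, None]
        theta = np.mod(np.arctan2(unit[:, 1], unit[:, 0]), TWO_PI)
        snapshots.append(
            VelocitySnapshot(
                time=fr * dt,
                cell_ids=cell_ids[keep],
                positions=pos[keep],
                velocities=vel,
                unit_velocities=unit,
                angles=theta,
            )
        )
    if n_zero:
        logger.warning("estimate_velocities: excluded %d zero-velocity cell-frame(s)", n_zero)
    return SnapshotSeries(snapshots, n_zero_velocity_excluded=n_zero)


def snapshots_from_angles(
    angles: np.ndarray, positions: np.ndarray, frame_interval: float = 10.0
) -> SnapshotSeries:
    """Wrap sampled angle configurations directly as velocity snapshots.

    Convenience bridge from equilibrium model samples (one realization per
    time point, unit speed) to the snapshot-based analysis stages.
    """
    angles = np.atleast_2d(np.asarray(angles, dtype=float))
    positions = np.asarray(positions, dtype=float)
    snaps = []
    for t, th in enumerate(angles):
        unit = np.stack([np.cos(th), np.sin(th)], axis=1)
        snaps.append(
            VelocitySnapshot(
                time=t * frame_interval,
                cell_ids=np.arange(positions.shape[0]),
                positions=positions,
                velocities=unit,
                unit_velocities=unit,
                angles=np.mod(th, TWO_PI),
            )
        )
    return SnapshotSeries(snaps)
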