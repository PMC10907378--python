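"""Core domain types and file I/O.

Coordinate convention used throughout the package: 0-based ``(row, col)``
pixel coordinates, origin at the top-left corner, with the center of a pixel
at an integer coordinate.  Movies are stored per channel as grayscale
multi-page TIFF stacks; tabular artifacts (detections, tracks, traces,
rasters) are plain CSV.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "TrackStatus",
    "Movie",
    "FrameDetections",
    "Track",
    "NeuronSignals",
    "SpikeRaster",
    "FormatError",
    "read_movie",
    "write_movie",
    "read_detections_csv",
    "write_detections_csv",
    "read_tracks_csv",
    "write_tracks_csv",
    "read_traces_csv",
    "write_traces_csv",
    "read_raster_csv",
    "write_raster_csv",
]


class FormatError(ValueError):
    """Raised when an on-disk artifact violates the expected format."""


class TrackStatus(enum.IntEnum):
    DETECTED = 0
    INTERPOLATED = 1


@dataclass
class Movie:
    """A single-channel T x H x W intensity stack.

    Parameters
    ----------
    frames:
        Array of shape ``(T, H, W)`` with finite, non-negative intensities.
    frame_rate_hz:
        Acquisition rate; defaults to 10 frames per second.
    channel_name:
        Either ``"anchor"`` (nuclear, calcium-insensitive) or ``"activity"``
        (cytoplasmic calcium indicator).
    """

    frames: np.ndarray
    frame_rate_hz: float = 10.0
    channel_name: str = "anchor"

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.float64)
        if self.frames.ndim != 3:
            raise ValueError(f"frames must be T x H x W, got shape {self.frames.shape}")
        if self.frames.shape[0] < 1:
            raise ValueError("movie must contain at least one frame")
        if not np.all(np.isfinite(self.frames)):
            raise ValueError("movie intensities must be finite")
        if np.any(self.frames < 0):
            raise ValueError("movie intensities must be non-negative")
        if not self.frame_rate_hz > 0:
            raise ValueError("frame_rate_hz must be positive")
        if self.channel_name not in ("anchor", "activity"):
            raise ValueError(f"unknown channel_name {self.channel_name!r}")

    @property
    def n_frames(self) -> int:
        return int(self.frames.shape[0])

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(self.frames.shape)  # type: ignore[return-value]


@dataclass
class FrameDetections:
    """Centroids and areas of objects segmented in one frame."""

    frame_index: int
    centroids: np.ndarray  # (N, 2) float, (row, col)
    areas: np.ndarray  # (N,) int pixel counts
    label_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.centroids = np.asarray(self.centroids, dtype=np.float64).reshape(-1, 2)
        self.areas = np.asarray(self.areas, dtype=np.int64).reshape(-1)
        if self.frame_index < 0:
            raise ValueError("frame_index must be >= 0")
        if len(self.centroids) != len(self.areas):
            raise ValueError("centroids and areas must have equal length")

    def __len__(self) -> int:
        return len(self.centroids)


@dataclass
class Track:
    """A single identity with per-frame positions over a contiguous span.

    ``start_frame`` and ``end_frame`` are 0-based and inclusive.  ``status``
    marks each frame as DETECTED (supported by a detection) or INTERPOLATED
    (filled during stitching / gap coasting).
    """

    track_id: int
    start_frame: int
    positions: np.ndarray  # (L, 2) float, (row, col)
    status: np.ndarray  # (L,) TrackStatus values
    parent_tracklets: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.float64).reshape(-1, 2)
        self.status = np.asarray(self.status, dtype=np.int64).reshape(-1)
        if self.start_frame < 0:
            raise ValueError("start_frame must be >= 0")
        if len(self.positions) < 1:
            raise ValueError("track must cover at least one frame")
        if len(self.positions) != len(self.status):
            raise ValueError("positions and status must have equal length")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("track positions must be defined on every covered frame")

    @property
    def end_frame(self) -> int:
        return self.start_frame + len(self.positions) - 1

    @property
    def n_frames(self) -> int:
        return len(self.positions)

    def position_at(self, frame: int) -> np.ndarray:
        if not self.start_frame <= frame <= self.end_frame:
            raise IndexError(f"frame {frame} outside track span")
        return self.positions[frame - self.start_frame]

    def status_at(self, frame: int) -> int:
        if not self.start_frame <= frame <= self.end_frame:
            raise IndexError(f"frame {frame} outside track span")
        return int(self.status[frame - self.start_frame])

    def covers(self, frame: int) -> bool:
        return self.start_frame <= frame <= self.end_frame


#: per-stage trace names in processing order
TRACE_STAGES = (
    "control",
    "calcium_raw",
    "calcium_ica",
    "calcium_detrended",
    "calcium_smoothed",
)


@dataclass
class NeuronSignals:
    """Per-neuron traces over the full movie span.

    Frames outside the neuron's track span are NaN (an explicit missing
    marker — never silently zero-filled, 0 being a legal intensity).
    """

    track_id: int
    control: np.ndarray
    calcium_raw: np.ndarray
    calcium_ica: np.ndarray | None = None
    calcium_detrended: np.ndarray | None = None
    calcium_smoothed: np.ndarray | None = None
    calcium_positions: np.ndarray | None = None  # (T, 2), NaN outside span

    def __post_init__(self) -> None:
        self.control = np.asarray(self.control, dtype=np.float64)
        self.calcium_raw = np.asarray(self.calcium_raw, dtype=np.float64)
        n = len(self.control)
        for name in ("calcium_raw", "calcium_ica", "calcium_detrended", "calcium_smoothed"):
            trace = getattr(self, name)
            if trace is not None and len(trace) != n:
                raise ValueError(f"{name} length {len(trace)} != control length {n}")

    @property
    def n_frames(self) -> int:
        return len(self.control)

    @property
    def span_mask(self) -> np.ndarray:
        """Boolean mask of frames inside the track span."""
        return ~np.isnan(self.calcium_raw)


@dataclass
class SpikeRaster:
    """Discrete predicted events ``(track_id, frame_index, amplitude)``."""

    events: list[tuple[int, int, float]]
    n_neurons: int
    n_frames: int

    def __post_init__(self) -> None:
        for tid, frame, amp in self.events:
            if not 0 <= frame < self.n_frames:
                raise ValueError(f"event frame {frame} outside [0, {self.n_frames})")
            if not amp > 0:
                raise ValueError("event amplitudes must be > 0")
        self.events = sorted(self.events, key=lambda e: (e[0], e[1]))

    def events_for(self, track_id: int) -> list[tuple[int, float]]:
        return [(f, a) for tid, f, a in self.events if tid == track_id]

    def to_dense(self, track_ids: Sequence[int] | None = None) -> np.ndarray:
        """Dense (n_neurons, n_frames) amplitude matrix (row order = sorted ids)."""
        ids = sorted({tid for tid, _, _ in self.events}) if track_ids is None else list(track_ids)
        out = np.zeros((len(ids), self.n_frames))
        index = {tid: i for i, tid in enumerate(ids)}
        for tid, frame, amp in self.events:
            if tid in index:
                out[index[tid], frame] += amp
        return out


# ---------------------------------------------------------------------------
# Movies


def read_movie(path: str | Path, frame_rate_hz: float = 10.0, channel_name: str = "anchor") -> Movie:
    """Read a grayscale multi-page TIFF into a :class:`Movie`.

    Pages must all share the same H x W shape; intensities are promoted to
    float64.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with tifffile.TiffFile(str(path)) as tif:
        pages = [page.asarray() for page in tif.pages]
    if not pages:
        raise FormatError(f"{path}: TIFF contains no pages")
    shape0 = pages[0].shape
    for i, page in enumerate(pages):
        if page.ndim != 2:
            raise FormatError(f"{path}: page {i} is not grayscale (shape {page.shape})")
        if page.shape != shape0:
            raise FormatError(
                f"{path}: page {i} has shape {page.shape}, expected {shape0}"
            )
    stack = np.stack(pages).astype(np.float64)
    return Movie(stack, frame_rate_hz=frame_rate_hz, channel_name=channel_name)


def write_movie(movie: Movie, path: str | Path) -> None:
    """Write a movie as a float32 multi-page TIFF."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(
        str(path), movie.frames.astype(np.float32), photometric="minisblack"
    )


# ---------------------------------------------------------------------------
# Detections


def write_detections_csv(detections: Iterable[FrameDetections], path: str | Path) -> None:
    rows = []
    for det in detections:
        for (r, c), area in zip(det.centroids, det.areas):
            rows.append((det.frame_index, r, c, int(area)))
    df = pd.DataFrame(rows, columns=["frame", "row", "col", "area"])
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format="%.6f")


def read_detections_csv(path: str | Path) -> list[FrameDetections]:
    df = pd.read_csv(path)
    expected = ["frame", "row", "col", "area"]
    if list(df.columns) != expected:
        raise FormatError(f"{path}: expected columns {expected}, got {list(df.columns)}")
    out = []
    if len(df) == 0:
        return out
    for frame, grp in df.groupby("frame", sort=True):
        out.append(
            FrameDetections(
                frame_index=int(frame),
                centroids=grp[["row", "col"]].to_numpy(),
                areas=grp["area"].to_numpy(),
            )
        )
    return out


# ---------------------------------------------------------------------------
# Tracks


def write_tracks_csv(tracks: Iterable[Track], path: str | Path) -> None:
    """Write tracks as CSV with columns track_id, frame, row, col, status."""
    rows = []
    for track in tracks:
        for offset in range(track.n_frames):
            r, c = track.positions[offset]
            rows.append(
                (
                    track.track_id,
                    track.start_frame + offset,
                    r,
                    c,
                    TrackStatus(track.status[offset]).name,
                )
            )
    df = pd.DataFrame(rows, columns=["track_id", "frame", "row", "col", "status"])
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format="%.6f")


def read_tracks_csv(path: str | Path) -> list[Track]:
    df = pd.read_csv(path)
    expected = ["track_id", "frame", "row", "col", "status"]
    if list(df.columns) != expected:
        raise FormatError(f"{path}: expected columns {expected}, got {list(df.columns)}")
    if df.duplicated(subset=["track_id", "frame"]).any():
        dup = df[df.duplicated(subset=["track_id", "frame"])].iloc[0]
        raise FormatError(
            f"{path}: duplicate (track_id, frame) row ({int(dup.track_id)}, {int(dup.frame)})"
        )
    tracks = []
    for tid, grp in df.groupby("track_id", sort=True):
        grp = grp.sort_values("frame")
        frames = grp["frame"].to_numpy()
        if len(frames) > 1 and not np.all(np.diff(frames) == 1):
            raise FormatError(f"{path}: track {tid} has non-contiguous frames")
        status = np.array([TrackStatus[s].value for s in grp["status"]])
        tracks.append(
            Track(
                track_id=int(tid),
                start_frame=int(frames[0]),
                positions=grp[["row", "col"]].to_numpy(),
                status=status,
            )
        )
    return tracks


# ---------------------------------------------------------------------------
# Traces


def write_traces_csv(signals: Iterable[NeuronSignals], path: str | Path) -> None:
    """Long-format CSV: track_id, frame, stage, value (missing frames omitted)."""
    rows = []
    for sig in signals:
        for stage in TRACE_STAGES:
            trace = getattr(sig, stage)
            if trace is None:
                continue
            for frame, value in enumerate(np.asarray(trace, dtype=float)):
                if not math.isnan(value):
                    rows.append((sig.track_id, frame, stage, value))
    df = pd.DataFrame(rows, columns=["track_id", "frame", "stage", "value"])
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format="%.9g")


def read_traces_csv(path: str | Path, n_frames: int) -> list[NeuronSignals]:
    df = pd.read_csv(path)
    expected = ["track_id", "frame", "stage", "value"]
    if list(df.columns) != expected:
        raise FormatError(f"{path}: expected columns {expected}, got {list(df.columns)}")
    out = []
    for tid, grp in df.groupby("track_id", sort=True):
        traces: dict[str, np.ndarray] = {
            stage: np.full(n_frames, np.nan) for stage in TRACE_STAGES
        }
        seen: set[str] = set()
        for _, row in grp.iterrows():
            traces[row.stage][int(row.frame)] = row.value
            seen.add(row.stage)
        out.append(
            NeuronSignals(
                track_id=int(tid),
                control=traces["control"],
                calcium_raw=traces["calcium_raw"],
                calcium_ica=traces["calcium_ica"] if "calcium_ica" in seen else None,
                calcium_detrended=(
                    traces["calcium_detrended"] if "calcium_detrended" in seen else None
                ),
                calcium_smoothed=(
                    traces["calcium_smoothed"] if "calcium_smoothed" in seen else None
                ),
            )
        )
    return out


# ---------------------------------------------------------------------------
# Raster


def write_raster_csv(raster: SpikeRaster, path: str | Path) -> None:
    df = pd.DataFrame(raster.events, columns=["track_id", "frame", "amplitude"])
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format="%.9g")


def read_raster_csv(path: str | Path, n_neurons: int, n_frames: int) -> SpikeRaster:
    df = pd.read_csv(path)
    expected = ["track_id", "frame", "amplitude"]
    if list(df.columns) != expected:
        raise FormatError(f"{path}: expected columns {expected}, got {list(df.columns)}")
    events = [
        (int(r.track_id), int(r.frame), float(r.amplitude)) for r in df.itertuples()
    ]
    return SpikeRaster(events=events, n_neurons=n_neurons, n_frames=n_frames)
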