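"""Conservative frame-to-frame linking of detections into tracklets.

Reference tracker behind a pluggable contract: a constant-velocity Kalman
filter per live tracklet, a gated min-cost one-to-one assignment per frame
(Jonker-Volgenant via ``scipy.optimize.linear_sum_assignment``), coasting of
unmatched tracklets for a bounded number of frames, and new tracklets seeded
from unmatched detections.  Any callable with the same
``(detections, params) -> list[Track]`` signature can replace it.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment

from .io import FrameDetections, Track, TrackStatus

__all__ = ["LinkerParams", "link_detections"]


@dataclass(frozen=True)
class LinkerParams:
    gate_radius_px: float = 10.0
    max_missed_frames: int = 5
    process_noise: float = 1.0
    measurement_noise: float = 0.5

    def __post_init__(self) -> None:
        if not self.gate_radius_px > 0:
            raise ValueError("gate_radius_px must be > 0")
        if self.max_missed_frames < 0:
            raise ValueError("max_missed_frames must be >= 0")
        if self.process_noise <= 0 or self.measurement_noise <= 0:
            raise ValueError("noise parameters must be > 0")


# state: (row, col, v_row, v_col); measurement: (row, col)
_F = np.array(
    [[1, 0, 1, 0], [0, 1, 0, 1], [0, 0, 1, 0], [0, 0, 0, 1]], dtype=float
)
_H = np.array([[1, 0, 0, 0], [0, 1, 0, 0]], dtype=float)


class _Tracklet:
    __slots__ = ("x", "P", "start_frame", "positions", "status", "missed")

    def __init__(self, position: np.ndarray, frame: int, params: LinkerParams):
        self.x = np.array([position[0], position[1], 0.0, 0.0])
        # inflated velocity covariance for a fresh tracklet
        self.P = np.diag(
            [
                params.measurement_noise**2,
                params.measurement_noise**2,
                params.gate_radius_px**2,
                params.gate_radius_px**2,
            ]
        )
        self.start_frame = frame
        self.positions = [np.asarray(position, dtype=float)]
        self.status = [int(TrackStatus.DETECTED)]
        self.missed = 0

    def predict(self, params: LinkerParams) -> None:
        q = params.process_noise**2
        Q = q * np.array(
            [
                [0.25, 0, 0.5, 0],
                [0, 0.25, 0, 0.5],
                [0.5, 0, 1.0, 0],
                [0, 0.5, 0, 1.0],
            ]
        )
        self.x = _F @ self.x
        self.P = _F @ self.P @ _F.T + Q

    @property
    def predicted_position(self) -> np.ndarray:
        return self.x[:2]

    def innovation_cov(self, params: LinkerParams) -> np.ndarray:
        return _H @ self.P @ _H.T + params.measurement_noise**2 * np.eye(2)

    def update(self, measurement: np.ndarray, params: LinkerParams) -> None:
        S = self.innovation_cov(params)
        K = self.P @ _H.T @ np.linalg.inv(S)
        y = measurement - _H @ self.x
        self.x = self.x + K @ y
        self.P = (np.eye(4) - K @ _H) @ self.P

    def append_detected(self, position: np.ndarray) -> None:
        self.positions.append(np.asarray(position, dtype=float))
        self.status.append(int(TrackStatus.DETECTED))
        self.missed = 0

    def append_coasted(self) -> None:
        self.positions.append(self.predicted_position.copy())
        self.status.append(int(TrackStatus.INTERPOLATED))
        self.missed += 1

    def finalize(self, track_id: int) -> Track | None:
        positions = np.array(self.positions)
        status = np.array(self.status)
        # trim the coasted tail back to the last DETECTED frame
        detected = np.flatnonzero(status == int(TrackStatus.DETECTED))
        if len(detected) == 0:
            return None
        last = detected[-1]
        return Track(
            track_id=track_id,
            start_frame=self.start_frame,
            positions=positions[: last + 1],
            status=status[: last + 1],
        )


# chi-square 99% quantile, 2 dof — Mahalanobis gate
_MAHA_GATE2 = 9.21
_FORBIDDEN = 1e9


def link_detections(
    detections: Sequence[FrameDetections], params: LinkerParams
) -> list[Track]:
    """Link per-frame detections into conservative tracklets.

    Frames where a tracklet coasts inside a gap shorter than
    ``max_missed_frames`` carry the Kalman-predicted position and are flagged
    INTERPOLATED; trailing coasted frames are trimmed.
    """
    detections = sorted(detections, key=lambda d: d.frame_index)
    live: list[_Tracklet] = []
    done: list[_Tracklet] = []
    by_frame = {d.frame_index: d for d in detections}
    if not detections:
        return []
    t_min = detections[0].frame_index
    t_max = detections[-1].frame_index

    for t in range(t_min, t_max + 1):
        points = (
            by_frame[t].centroids if t in by_frame else np.empty((0, 2), dtype=float)
        )
        for trk in live:
            if t > trk.start_frame:
                trk.predict(params)

        n, m = len(live), len(points)
        matched_tracks = np.full(n, -1)
        matched_dets = np.zeros(m, dtype=bool)
        if n and m:
            cost = np.full((n, m), _FORBIDDEN)
            for i, trk in enumerate(live):
                delta = points - trk.predicted_position
                dist = np.linalg.norm(delta, axis=1)
                S_inv = np.linalg.inv(trk.innovation_cov(params))
                maha2 = np.einsum("nj,jk,nk->n", delta, S_inv, delta)
                ok = (dist <= params.gate_radius_px) & (maha2 <= _MAHA_GATE2)
                cost[i, ok] = dist[ok]
            # pad to allow non-assignment at gate cost
            size = n + m
            padded = np.full((size, size), 0.0)
            padded[:n, :m] = cost
            padded[:n, m:] = _FORBIDDEN
            padded[n:, :m] = _FORBIDDEN
            padded[np.arange(n), m + np.arange(n)] = params.gate_radius_px
            padded[n + np.arange(m), np.arange(m)] = params.gate_radius_px
            rows, cols = linear_sum_assignment(padded)
            for i, j in zip(rows, cols):
                if i < n and j < m and cost[i, j] < _FORBIDDEN:
                    matched_tracks[i] = j
                    matched_dets[j] = True

        survivors: list[_Tracklet] = []
        for i, trk in enumerate(live):
            j = matched_tracks[i]
            if j >= 0:
                trk.update(points[j], params)
                trk.append_detected(points[j])
                survivors.append(trk)
            else:
                trk.append_coasted()
                if trk.missed > params.max_missed_frames:
                    done.append(trk)
                else:
                    survivors.append(trk)
        live = survivors
        for j in range(m):
            if not matched_dets[j]:
                live.append(_Tracklet(points[j], t, params))

    done.extend(live)
    tracks = []
    next_id = 0
    for trk in sorted(done, key=lambda tr: (tr.start_frame, tr.positions[0][0], tr.positions[0][1])):
        track = trk.finalize(next_id)
        if track is not None:
            tracks.append(track)
            next_id += 1
    return tracks
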