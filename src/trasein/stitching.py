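"""Tracklet stitching by thin-plate-spline propagation and global assignment.

When a tracklet ends prematurely, the position of its (undetected) particle
is propagated forward one frame-step at a time with a smoothed thin-plate
spline fitted on tracklets detected at both ends of the step; symmetrically,
positions are propagated backward from tracklet starts.  The stitch cost of
an admissible ordered pair is the minimal distance between the forward and
backward estimates over the frames where both exist.  The global linking that
minimizes total cost (with a non-linking cost ``eta_px`` per unlinked
tracklet) is a linear assignment problem solved with the Jonker-Volgenant
algorithm; linked chains are merged, gap frames being filled with propagated
positions flagged INTERPOLATED.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment

from .io import Track, TrackStatus
from .tps import DegenerateControlPointsError, ThinPlateSpline

__all__ = [
    "StitchParams",
    "StitchCostMatrix",
    "tps_fit",
    "propagate_forward",
    "propagate_backward",
    "build_stitch_costs",
    "stitch",
]

_BIG = 1e12


@dataclass(frozen=True)
class StitchParams:
    alpha: float = 10.0
    eta_px: float = 5.0
    max_gap_frames: int = 50
    min_neighbors: int = 4

    def __post_init__(self) -> None:
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")
        if not self.eta_px > 0:
            raise ValueError("eta_px must be > 0")
        if self.max_gap_frames < 1:
            raise ValueError("max_gap_frames must be >= 1")
        if self.min_neighbors < 3:
            raise ValueError("min_neighbors must be >= 3")


@dataclass
class StitchCostMatrix:
    tracklet_ids: list[int]
    costs: np.ndarray  # (n, n), np.inf where linking is forbidden


def tps_fit(
    source_points: np.ndarray, target_points: np.ndarray, alpha: float
) -> ThinPlateSpline:
    """Fit a smoothed TPS map; raises on degenerate control points."""
    return ThinPlateSpline(source_points, target_points, alpha=alpha)


def _detected_position(track: Track, frame: int) -> np.ndarray | None:
    if not track.covers(frame):
        return None
    if track.status_at(frame) != int(TrackStatus.DETECTED):
        return None
    return track.position_at(frame)


class _StepFitCache:
    """Caches per-frame-step TPS fits over a tracklet population."""

    def __init__(self, tracklets: list[Track], params: StitchParams):
        self.tracklets = tracklets
        self.params = params
        self._cache: dict[tuple[int, int], ThinPlateSpline | None] = {}

    def fit(self, t_from: int, t_to: int) -> ThinPlateSpline | None:
        """TPS mapping positions at ``t_from`` to positions at ``t_to``.

        Returns None when fewer than ``min_neighbors`` control pairs exist
        or the configuration is degenerate.
        """
        key = (t_from, t_to)
        if key not in self._cache:
            src, dst = [], []
            for track in self.tracklets:
                p = _detected_position(track, t_from)
                q = _detected_position(track, t_to)
                if p is not None and q is not None:
                    src.append(p)
                    dst.append(q)
            if len(src) < self.params.min_neighbors:
                self._cache[key] = None
            else:
                try:
                    self._cache[key] = ThinPlateSpline(
                        np.array(src), np.array(dst), alpha=self.params.alpha
                    )
                except DegenerateControlPointsError:
                    self._cache[key] = None
        return self._cache[key]


def _propagate(
    track: Track,
    cache: _StepFitCache,
    params: StitchParams,
    n_frames: int,
    forward: bool,
    frame_bound: int,
) -> dict[int, np.ndarray]:
    """Iterated one-step TPS propagation from a tracklet terminus.

    Returns ``{frame: estimated position}`` including the terminus frame
    itself (with the actual position).  Truncated as soon as a step lacks
    enough neighbors.
    """
    anchor_frame = track.end_frame if forward else track.start_frame
    estimates = {anchor_frame: track.position_at(anchor_frame).copy()}
    pos = estimates[anchor_frame]
    step = 1 if forward else -1
    frame = anchor_frame
    for _ in range(n_frames):
        nxt = frame + step
        if forward and nxt > frame_bound:
            break
        if not forward and nxt < frame_bound:
            break
        warp = cache.fit(frame, nxt)
        if warp is None:
            break
        pos = warp(pos)
        estimates[nxt] = pos
        frame = nxt
    return estimates


def propagate_forward(
    tracklet: Track,
    all_tracklets: list[Track],
    params: StitchParams,
    n_frames: int,
    frame_bound: int | None = None,
) -> dict[int, np.ndarray]:
    """Estimated positions after the tracklet's end (keyed by frame)."""
    cache = _StepFitCache(
        [t for t in all_tracklets if t is not tracklet], params
    )
    if frame_bound is None:
        frame_bound = max(t.end_frame for t in all_tracklets)
    return _propagate(tracklet, cache, params, n_frames, True, frame_bound)


def propagate_backward(
    tracklet: Track,
    all_tracklets: list[Track],
    params: StitchParams,
    n_frames: int,
    frame_bound: int = 0,
) -> dict[int, np.ndarray]:
    """Estimated positions before the tracklet's start (keyed by frame)."""
    cache = _StepFitCache(
        [t for t in all_tracklets if t is not tracklet], params
    )
    return _propagate(tracklet, cache, params, n_frames, False, frame_bound)


def _all_propagations(
    tracklets: list[Track], params: StitchParams
) -> tuple[list[dict[int, np.ndarray]], list[dict[int, np.ndarray]]]:
    cache = _StepFitCache(tracklets, params)
    t_max = max(t.end_frame for t in tracklets)
    forward = [
        _propagate(t, cache, params, params.max_gap_frames, True, t_max)
        for t in tracklets
    ]
    backward = [
        _propagate(t, cache, params, params.max_gap_frames, False, 0)
        for t in tracklets
    ]
    return forward, backward


def build_stitch_costs(
    tracklets: list[Track], params: StitchParams
) -> StitchCostMatrix:
    """Pairwise stitch costs: minimal forward/backward estimate distance.

    ``cost[i, j]`` is finite only when tracklet j starts strictly after
    tracklet i ends, the temporal gap is at most ``max_gap_frames``, and the
    two propagations overlap on at least one frame.
    """
    n = len(tracklets)
    costs = np.full((n, n), np.inf)
    if n == 0:
        return StitchCostMatrix([], costs)
    forward, backward = _all_propagations(tracklets, params)
    for i, ti in enumerate(tracklets):
        for j, tj in enumerate(tracklets):
            if i == j or tj.start_frame <= ti.end_frame:
                continue
            gap = tj.start_frame - ti.end_frame - 1
            if gap > params.max_gap_frames:
                continue
            common = sorted(set(forward[i]) & set(backward[j]))
            if not common:
                continue
            d = min(
                float(np.linalg.norm(forward[i][t] - backward[j][t]))
                for t in common
            )
            costs[i, j] = d
    return StitchCostMatrix([t.track_id for t in tracklets], costs)


def _solve_links(costs: np.ndarray, eta_px: float) -> dict[int, int]:
    """Global assignment: link i -> j iff beneficial versus paying eta."""
    n = len(costs)
    if n == 0:
        return {}
    half_eta = eta_px / 2.0
    full = np.full((2 * n, 2 * n), _BIG)
    tl = np.where(np.isfinite(costs), costs, _BIG)
    full[:n, :n] = tl
    full[np.arange(n), n + np.arange(n)] = half_eta
    full[n + np.arange(n), np.arange(n)] = half_eta
    br = np.where(np.isfinite(costs.T), 0.0, _BIG)
    full[n:, n:] = br
    rows, cols = linear_sum_assignment(full)
    links = {}
    for i, j in zip(rows, cols):
        if i < n and j < n and np.isfinite(costs[i, j]) and full[i, j] < _BIG:
            links[i] = j
    return links


def _fill_gap(
    ti: Track,
    tj: Track,
    fwd: dict[int, np.ndarray],
    bwd: dict[int, np.ndarray],
) -> tuple[np.ndarray, np.ndarray]:
    """Positions and statuses for the frames strictly between two tracklets."""
    frames = range(ti.end_frame + 1, tj.start_frame)
    positions, statuses = [], []
    p0 = ti.position_at(ti.end_frame)
    p1 = tj.position_at(tj.start_frame)
    span = tj.start_frame - ti.end_frame
    for t in frames:
        have_f = t in fwd
        have_b = t in bwd
        if have_f and have_b:
            pos = 0.5 * (fwd[t] + bwd[t])
        elif have_f:
            pos = fwd[t]
        elif have_b:
            pos = bwd[t]
        else:
            w = (t - ti.end_frame) / span
            pos = (1 - w) * p0 + w * p1
        positions.append(pos)
        statuses.append(int(TrackStatus.INTERPOLATED))
    return np.array(positions).reshape(-1, 2), np.array(statuses, dtype=np.int64)


def stitch(tracklets: list[Track], params: StitchParams) -> list[Track]:
    """Merge tracklets of the same particle into long tracks.

    Chains found by the global assignment are merged transitively; gap frames
    carry the average of the forward and backward propagated estimates (or
    whichever exists, falling back to linear interpolation) and are flagged
    INTERPOLATED.
    """
    if not tracklets:
        return []
    costs = build_stitch_costs(tracklets, params).costs
    links = _solve_links(costs, params.eta_px)
    forward, backward = _all_propagations(tracklets, params)

    has_pred = set(links.values())
    out: list[Track] = []
    next_id = 0
    for i in range(len(tracklets)):
        if i in has_pred:
            continue
        chain = [i]
        while chain[-1] in links:
            chain.append(links[chain[-1]])
        positions = [tracklets[chain[0]].positions]
        statuses = [tracklets[chain[0]].status]
        for a, b in zip(chain[:-1], chain[1:]):
            gap_pos, gap_status = _fill_gap(
                tracklets[a], tracklets[b], forward[a], backward[b]
            )
            if len(gap_pos):
                positions.append(gap_pos)
                statuses.append(gap_status)
            positions.append(tracklets[b].positions)
            statuses.append(tracklets[b].status)
        out.append(
            Track(
                track_id=next_id,
                start_frame=tracklets[chain[0]].start_frame,
                positions=np.concatenate(positions, axis=0),
                status=np.concatenate(statuses),
                parent_tracklets=[tracklets[k].track_id for k in chain],
            )
        )
        next_id += 1
    return out
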