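"""Locating cell bodies in the misaligned activity channel and extracting traces.

For each tracked nucleus a small ROI is cut out of the activity channel,
smoothed, weighted by a Gaussian prior centered on the nucleus, and its top
local maxima extracted by iterated peak-picking with disc suppression.  The
calcium position follows the maximum closest to its previous estimate through
an exponential moving average, and per-frame intensities are disc means
around the calcium (activity) and nucleus (anchor) positions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .io import Movie, NeuronSignals, Track

__all__ = [
    "SubRoiParams",
    "find_roi_maxima",
    "track_calcium_positions",
    "extract_signals",
    "disc_mean",
]


@dataclass(frozen=True)
class SubRoiParams:
    roi_size_px: int = 25
    n_maxima: int = 5
    smooth_sigma_px: float = 1.0
    prior_sigma_px: float = 5.0
    extract_radius_px: float = 5.0
    ema_rate: float = 0.5
    suppression_radius_px: float = 3.0

    def __post_init__(self) -> None:
        if self.roi_size_px % 2 != 1:
            raise ValueError("roi_size_px must be odd")
        if self.roi_size_px < 2 * self.extract_radius_px + 1:
            raise ValueError("roi_size_px must be >= 2*extract_radius_px + 1")
        if self.n_maxima < 1:
            raise ValueError("n_maxima must be >= 1")
        if not 0 < self.ema_rate <= 1:
            raise ValueError("ema_rate must be in (0, 1]")


def find_roi_maxima(roi: np.ndarray, params: SubRoiParams) -> list[tuple[int, int]]:
    """Ordered prior-weighted local maxima of an ROI patch.

    The patch is Gaussian-smoothed, multiplied by a Gaussian prior centered
    on the patch center, and the global maximum is extracted ``n_maxima``
    times, zeroing a suppression disc around each pick.  The prior decides
    which peak is picked; each pick is then refined to the brightest pixel of
    the unweighted smoothed patch within the suppression radius, so the
    reported position is the cell's own intensity peak, not the prior-shifted
    one (ties keep the weighted pick).
    """
    roi = np.asarray(roi, dtype=np.float64)
    smoothed = ndimage.gaussian_filter(roi, params.smooth_sigma_px, mode="nearest")
    h, w = roi.shape
    cr, cc = (h - 1) / 2.0, (w - 1) / 2.0
    rr = np.arange(h)[:, None] - cr
    cc_ = np.arange(w)[None, :] - cc
    prior = np.exp(-(rr**2 + cc_**2) / (2 * params.prior_sigma_px**2))
    weighted = smoothed * prior
    maxima: list[tuple[int, int]] = []
    work = weighted.copy()
    for _ in range(params.n_maxima):
        idx = np.unravel_index(np.argmax(work), work.shape)
        dr = np.arange(h)[:, None] - idx[0]
        dc = np.arange(w)[None, :] - idx[1]
        near = dr**2 + dc**2 <= params.suppression_radius_px**2
        local = np.where(near, smoothed, -np.inf)
        best = np.unravel_index(np.argmax(local), local.shape)
        if local[best] > local[idx]:
            idx = best
        maxima.append((int(idx[0]), int(idx[1])))
        dr = np.arange(h)[:, None] - idx[0]
        dc = np.arange(w)[None, :] - idx[1]
        work[dr**2 + dc**2 <= params.suppression_radius_px**2] = -np.inf
        if np.all(np.isneginf(work)):
            break
    return maxima


def _extract_patch(frame: np.ndarray, center: np.ndarray, size: int) -> tuple[np.ndarray, np.ndarray]:
    """Square patch of odd ``size`` centered at the rounded center.

    Edge-clipped patches are padded by edge replication.  Returns the patch
    and the (row, col) image coordinates of its top-left pixel.
    """
    half = size // 2
    r0 = int(round(center[0])) - half
    c0 = int(round(center[1])) - half
    H, W = frame.shape
    pad_top = max(0, -r0)
    pad_left = max(0, -c0)
    pad_bottom = max(0, r0 + size - H)
    pad_right = max(0, c0 + size - W)
    patch = frame[
        max(r0, 0) : min(r0 + size, H), max(c0, 0) : min(c0 + size, W)
    ]
    if pad_top or pad_left or pad_bottom or pad_right:
        patch = np.pad(patch, ((pad_top, pad_bottom), (pad_left, pad_right)), mode="edge")
    return patch, np.array([r0, c0], dtype=float)


def track_calcium_positions(
    track: Track, activity: Movie, params: SubRoiParams
) -> np.ndarray:
    """Per-frame calcium position estimates over the track span, (L, 2).

    The first frame takes the top prior-weighted maximum; subsequent frames
    take the candidate nearest the previous calcium position blended by an
    exponential moving average.
    """
    positions = np.empty((track.n_frames, 2))
    prev: np.ndarray | None = None
    for offset in range(track.n_frames):
        frame_idx = track.start_frame + offset
        nucleus = track.positions[offset]
        frame = activity.frames[frame_idx]
        patch, origin = _extract_patch(frame, nucleus, params.roi_size_px)
        maxima = find_roi_maxima(patch, params)
        candidates = np.array(maxima, dtype=float) + origin
        if prev is None:
            pos = candidates[0]
        else:
            nearest = candidates[np.argmin(np.linalg.norm(candidates - prev, axis=1))]
            pos = (1.0 - params.ema_rate) * prev + params.ema_rate * nearest
        H, W = frame.shape
        pos = np.clip(pos, [0.0, 0.0], [H - 1.0, W - 1.0])
        positions[offset] = pos
        prev = pos
    return positions


def disc_mean(frame: np.ndarray, center: np.ndarray, radius: float) -> float:
    """Mean intensity over in-bounds pixels whose centers lie within radius."""
    H, W = frame.shape
    r0 = int(np.floor(center[0] - radius))
    r1 = int(np.ceil(center[0] + radius)) + 1
    c0 = int(np.floor(center[1] - radius))
    c1 = int(np.ceil(center[1] + radius)) + 1
    r0, r1 = max(r0, 0), min(r1, H)
    c0, c1 = max(c0, 0), min(c1, W)
    if r0 >= r1 or c0 >= c1:
        return float("nan")
    rr = np.arange(r0, r1)[:, None] - center[0]
    cc = np.arange(c0, c1)[None, :] - center[1]
    mask = rr**2 + cc**2 <= radius**2
    if not mask.any():
        return float("nan")
    return float(frame[r0:r1, c0:c1][mask].mean())


def extract_signals(
    track: Track,
    anchor: Movie,
    activity: Movie,
    params: SubRoiParams,
    calcium_positions: np.ndarray | None = None,
) -> NeuronSignals:
    """Raw calcium and control traces for one track over the full movie span.

    ``calcium_raw[t]`` is the activity-channel disc mean at the tracked
    calcium position and ``control[t]`` the anchor-channel disc mean at the
    nucleus position; frames outside the track span are NaN.
    """
    T = anchor.n_frames
    if track.end_frame >= T:
        raise ValueError(
            f"track spans frame {track.end_frame} but movie has {T} frames"
        )
    if calcium_positions is None:
        calcium_positions = track_calcium_positions(track, activity, params)
    if len(calcium_positions) != track.n_frames:
        raise ValueError("calcium_positions must cover the track span")

    control = np.full(T, np.nan)
    calcium_raw = np.full(T, np.nan)
    full_positions = np.full((T, 2), np.nan)
    for offset in range(track.n_frames):
        t = track.start_frame + offset
        control[t] = disc_mean(
            anchor.frames[t], track.positions[offset], params.extract_radius_px
        )
        calcium_raw[t] = disc_mean(
            activity.frames[t], calcium_positions[offset], params.extract_radius_px
        )
        full_positions[t] = calcium_positions[offset]
    return NeuronSignals(
        track_id=track.track_id,
        control=control,
        calcium_raw=calcium_raw,
        calcium_positions=full_positions,
    )
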