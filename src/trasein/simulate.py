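"""Synthetic two-channel movies of a deforming pseudo-animal with ground truth.

The generator emulates the statistical structure the tracking/signal pipeline
assumes: an elongated body of cells (denser at the two ends), slow smooth
non-rigid deformation driven by a thin-plate spline over a control grid, fast
contraction phases pulling cells toward the body center, constant-intensity
nuclear spots in the anchor channel, offset cytoplasmic cell bodies with
AR(2) calcium transients in the activity channel, photobleaching, shared
multiplicative motion-artifact dips, and Gaussian camera noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .io import Movie, Track, TrackStatus
from .tps import ThinPlateSpline

__all__ = [
    "SimConfig",
    "GroundTruth",
    "SimulationError",
    "default_ar2_coefficients",
    "simulate_movie",
    "fragment_tracks",
]

NEURON = "NEURON"
NEMATOCYTE = "NEMATOCYTE"


class SimulationError(RuntimeError):
    pass


def default_ar2_coefficients(
    rise_frames: float = 3.0, decay_frames: float = 20.0
) -> tuple[float, float]:
    """AR(2) coefficients from rise/decay time constants (in frames).

    The two kernel poles are ``exp(-1/tau)`` for each time constant, giving a
    slow-indicator-like difference-of-exponentials impulse response.
    """
    p_rise = float(np.exp(-1.0 / rise_frames))
    p_decay = float(np.exp(-1.0 / decay_frames))
    return p_rise + p_decay, -p_rise * p_decay


def ar2_poles(g1: float, g2: float) -> tuple[complex, complex]:
    """Roots of z^2 - g1 z - g2 (the AR(2) kernel poles)."""
    return tuple(np.roots([1.0, -g1, -g2]))  # type: ignore[return-value]


@dataclass
class SimConfig:
    """Full parameterization of a synthetic two-channel movie."""

    n_neurons: int = 30
    n_nematocytes: int = 2
    image_shape: tuple[int, int] = (128, 160)
    n_frames: int = 200
    frame_rate_hz: float = 10.0
    deformation_amplitude_px: float = 3.0
    contraction_windows: list[tuple[int, int]] = field(default_factory=list)
    spike_rate_hz: float = 0.1
    refractory_frames: int = 10
    calcium_g1: float = field(default_factory=lambda: default_ar2_coefficients()[0])
    calcium_g2: float = field(default_factory=lambda: default_ar2_coefficients()[1])
    calcium_transient_amplitude: float = 30.0
    baseline_activity: float = 12.0
    plateau_amplitude: float = 40.0
    noise_sigma_anchor: float = 1.0
    noise_sigma_activity: float = 1.0
    bleach_rate_anchor: float = 0.0
    bleach_rate_activity: float = 0.0
    channel_offset: tuple[float, float] = (3.0, 2.0)
    offset_jitter_sigma: float = 0.3
    artifact_rate_hz: float = 0.0
    artifact_depth: float = 0.5
    nuclear_amplitude: float = 50.0
    nuclear_sigma_px: float = 2.0
    body_sigma_px: float = 4.0
    background: float = 5.0
    min_spacing_px: float = 6.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_neurons < 0 or self.n_nematocytes < 0:
            raise ValueError("cell counts must be >= 0")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if not (0 <= self.artifact_depth < 1):
            raise ValueError("artifact_depth must be in [0, 1)")
        for rate in (self.spike_rate_hz, self.artifact_rate_hz,
                     self.bleach_rate_anchor, self.bleach_rate_activity):
            if rate < 0:
                raise ValueError("rates must be >= 0")
        poles = ar2_poles(self.calcium_g1, self.calcium_g2)
        for p in poles:
            if abs(p.imag) > 1e-12 or not (0 < p.real < 1):
                raise ValueError(
                    f"calcium AR(2) kernel poles {poles} must be real and in (0, 1)"
                )
        for start, end in self.contraction_windows:
            if not (0 <= start < end <= self.n_frames):
                raise ValueError(f"invalid contraction window ({start}, {end})")

    @property
    def n_cells(self) -> int:
        return self.n_neurons + self.n_nematocytes


@dataclass
class GroundTruth:
    """Per-cell, per-frame truth for every simulated quantity."""

    positions_anchor: np.ndarray  # (n_cells, T, 2)
    positions_activity: np.ndarray  # (n_cells, T, 2)
    spike_frames: list[np.ndarray]  # per cell, sorted frame indices (empty for nematocytes)
    cell_class: list[str]
    region: list[str]  # {"foot", "body", "head"}
    calcium: np.ndarray  # (n_cells, T) noiseless calcium trace
    artifact_factor: np.ndarray  # (n_cells, T) multiplicative shared factor
    control_grid: np.ndarray  # (n_ctrl, 2) base TPS control points
    deformation_fields: np.ndarray  # (T, n_ctrl, 2) displaced control points

    @property
    def n_cells(self) -> int:
        return self.positions_anchor.shape[0]

    @property
    def n_frames(self) -> int:
        return self.positions_anchor.shape[1]


# ---------------------------------------------------------------------------
# layout


def _sample_layout(config: SimConfig, rng: np.random.Generator) -> tuple[np.ndarray, list[str]]:
    """Elongated elliptical body with denser foot (left) and head (right) ends."""
    H, W = config.image_shape
    center = np.array([H / 2.0, W / 2.0])
    semi = np.array([0.30 * H, 0.42 * W])  # (row, col) semi-axes
    n = config.n_cells
    # a third of the cells in each end cluster, the rest spread over the body
    cluster_frac = 1.0 / 3.0
    positions: list[np.ndarray] = []
    max_tries = 400 * max(n, 1)
    tries = 0
    while len(positions) < n:
        tries += 1
        if tries > max_tries:
            raise SimulationError(
                f"could not place {n} cells with spacing {config.min_spacing_px} px "
                f"in a {H}x{W} image; use fewer cells or a larger image"
            )
        u = rng.random()
        if u < cluster_frac:  # foot
            col_frac = rng.uniform(-1.0, -0.6)
        elif u < 2 * cluster_frac:  # head
            col_frac = rng.uniform(0.6, 1.0)
        else:
            col_frac = rng.uniform(-1.0, 1.0)
        row_extent = np.sqrt(max(0.0, 1.0 - col_frac**2))
        row_frac = rng.uniform(-row_extent, row_extent)
        pos = center + np.array([row_frac * semi[0], col_frac * semi[1]])
        if positions and np.min(
            np.linalg.norm(np.array(positions) - pos, axis=1)
        ) < config.min_spacing_px:
            continue
        positions.append(pos)
    pts = np.array(positions).reshape(n, 2)
    if n >= 2:
        diff = pts[:, None] - pts[None, :]
        dist = np.sqrt((diff**2).sum(-1)) + np.eye(n) * 1e9
        if dist.min() < 1.0:
            raise SimulationError(
                "cells closer than 1 px at t=0; use fewer cells or more spacing"
            )
    rel_col = (pts[:, 1] - center[1]) / semi[1]
    region = ["foot" if rc < -1 / 3 else "head" if rc > 1 / 3 else "body" for rc in rel_col]
    return pts, region


def _control_grid(shape: tuple[int, int]) -> np.ndarray:
    H, W = shape
    rows = np.linspace(0, H - 1, 4)
    cols = np.linspace(0, W - 1, 5)
    rr, cc = np.meshgrid(rows, cols, indexing="ij")
    return np.column_stack([rr.ravel(), cc.ravel()])


def _deformation_series(
    config: SimConfig, grid: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Smooth per-control-point displacement time series, (T, n_ctrl, 2)."""
    T = config.n_frames
    n_ctrl = len(grid)
    t = np.arange(T)
    disp = np.zeros((T, n_ctrl, 2))
    if config.deformation_amplitude_px > 0:
        for axis in range(2):
            for m, (period_lo, period_hi, weight) in enumerate(
                [(150.0, 400.0, 1.0), (60.0, 150.0, 0.5)]
            ):
                period = rng.uniform(period_lo, period_hi, size=n_ctrl)
                phase = rng.uniform(0, 2 * np.pi, size=n_ctrl)
                disp[:, :, axis] += weight * np.sin(
                    2 * np.pi * t[:, None] / period[None, :] + phase[None, :]
                )
        disp *= config.deformation_amplitude_px / 1.5
    return disp


def _contraction_scale(config: SimConfig, t: int) -> float:
    """Fractional shrink toward the body center at frame t (0 = no contraction)."""
    for start, end in config.contraction_windows:
        if start <= t < end:
            tau = (t - start) / max(end - start - 1, 1)
            return float(np.sin(np.pi * tau) ** 2)
    return 0.0


# ---------------------------------------------------------------------------
# signals


def _simulate_calcium(
    config: SimConfig, rng: np.random.Generator
) -> tuple[np.ndarray, list[np.ndarray]]:
    """Noiseless calcium traces (n_cells, T) and per-cell spike frames."""
    T = config.n_frames
    traces = np.zeros((config.n_cells, T))
    spikes: list[np.ndarray] = []
    p_spike = config.spike_rate_hz / config.frame_rate_hz
    for i in range(config.n_cells):
        if i < config.n_neurons:
            s = rng.random(T) < p_spike
            # refractory period: drop spikes too close to their predecessor
            frames_raw = np.flatnonzero(s)
            frames_list: list[int] = []
            for f in frames_raw:
                if not frames_list or f - frames_list[-1] > config.refractory_frames:
                    frames_list.append(int(f))
            frames = np.array(frames_list, dtype=np.int64)
            s = np.zeros(T, dtype=bool)
            s[frames] = True
            c = np.zeros(T)
            for t in range(T):
                c[t] = (
                    config.calcium_g1 * (c[t - 1] if t >= 1 else 0.0)
                    + config.calcium_g2 * (c[t - 2] if t >= 2 else 0.0)
                    + (config.calcium_transient_amplitude if s[t] else 0.0)
                )
            traces[i] = c
            spikes.append(frames.astype(np.int64))
        else:
            # nematocyte-like plateau: single onset, stays elevated
            onset = int(rng.integers(T // 10 + 1, max(T // 2, T // 10 + 2)))
            t = np.arange(T, dtype=float)
            rise = 1.0 - np.exp(-(t - onset) / 5.0)
            traces[i] = np.where(t >= onset, config.plateau_amplitude * rise, 0.0)
            spikes.append(np.array([], dtype=np.int64))
    return traces, spikes


def _simulate_artifacts(
    config: SimConfig, positions0: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Multiplicative per-cell factor (n_cells, T); local dips shared by channels."""
    T = config.n_frames
    factor = np.ones((config.n_cells, T))
    duration_s = T / config.frame_rate_hz
    n_events = rng.poisson(config.artifact_rate_hz * duration_s)
    H, W = config.image_shape
    for _ in range(n_events):
        t0 = int(rng.integers(0, T))
        dur = int(rng.integers(3, 11))
        center = np.array([rng.uniform(0, H), rng.uniform(0, W)])
        radius = rng.uniform(0.15, 0.35) * min(H, W)
        affected = np.linalg.norm(positions0 - center, axis=1) < radius
        factor[affected, t0 : min(t0 + dur, T)] *= 1.0 - config.artifact_depth
    return factor


# ---------------------------------------------------------------------------
# rendering


def _render_frame(
    shape: tuple[int, int],
    positions: np.ndarray,
    amplitudes: np.ndarray,
    sigma: float,
) -> np.ndarray:
    H, W = shape
    frame = np.zeros((H, W))
    half = int(np.ceil(4 * sigma))
    for (r0, c0), amp in zip(positions, amplitudes):
        if amp == 0:
            continue
        r_lo = max(int(np.floor(r0)) - half, 0)
        r_hi = min(int(np.ceil(r0)) + half + 1, H)
        c_lo = max(int(np.floor(c0)) - half, 0)
        c_hi = min(int(np.ceil(c0)) + half + 1, W)
        if r_lo >= r_hi or c_lo >= c_hi:
            continue
        rr = np.arange(r_lo, r_hi)[:, None] - r0
        cc = np.arange(c_lo, c_hi)[None, :] - c0
        frame[r_lo:r_hi, c_lo:c_hi] += amp * np.exp(
            -(rr**2 + cc**2) / (2 * sigma**2)
        )
    return frame


# ---------------------------------------------------------------------------
# main entry points


def simulate_movie(config: SimConfig) -> tuple[Movie, Movie, GroundTruth]:
    """Generate (anchor movie, activity movie, ground truth) from ``config``.

    Deterministic given ``config.rng_seed``.
    """
    rng = np.random.default_rng(config.rng_seed)
    H, W = config.image_shape
    T = config.n_frames
    center = np.array([H / 2.0, W / 2.0])

    positions0, region = _sample_layout(config, rng)
    grid = _control_grid(config.image_shape)
    disp = _deformation_series(config, grid, rng)

    positions_anchor = np.empty((config.n_cells, T, 2))
    deformation_fields = np.empty((T, len(grid), 2))
    for t in range(T):
        displaced = grid + disp[t]
        deformation_fields[t] = displaced
        if config.deformation_amplitude_px > 0:
            warp = ThinPlateSpline(grid, displaced, alpha=0.0)
            pos = warp(positions0)
        else:
            pos = positions0.copy()
        shrink = _contraction_scale(config, t)
        if shrink > 0:
            a = config.deformation_amplitude_px / (0.42 * W)
            pos = pos.copy()
            pos[:, 1] = center[1] + (pos[:, 1] - center[1]) * (1.0 - a * shrink)
        pos[:, 0] = np.clip(pos[:, 0], 1.0, H - 2.0)
        pos[:, 1] = np.clip(pos[:, 1], 1.0, W - 2.0)
        positions_anchor[:, t] = pos

    jitter = rng.normal(0.0, config.offset_jitter_sigma, size=(config.n_cells, 2))
    offset = np.asarray(config.channel_offset, dtype=float)
    positions_activity = positions_anchor + (offset + jitter)[:, None, :]
    positions_activity[..., 0] = np.clip(positions_activity[..., 0], 1.0, H - 2.0)
    positions_activity[..., 1] = np.clip(positions_activity[..., 1], 1.0, W - 2.0)

    calcium, spike_frames = _simulate_calcium(config, rng)
    artifact = _simulate_artifacts(config, positions0, rng)

    bleach_anchor = np.exp(-config.bleach_rate_anchor * np.arange(T))
    bleach_activity = np.exp(-config.bleach_rate_activity * np.arange(T))

    anchor_frames = np.empty((T, H, W))
    activity_frames = np.empty((T, H, W))
    for t in range(T):
        amp_anchor = config.nuclear_amplitude * artifact[:, t]
        spots = _render_frame(
            config.image_shape, positions_anchor[:, t], amp_anchor, config.nuclear_sigma_px
        )
        frame = (config.background + spots) * bleach_anchor[t]
        if config.noise_sigma_anchor > 0:
            frame = frame + rng.normal(0, config.noise_sigma_anchor, size=(H, W))
        anchor_frames[t] = np.maximum(frame, 0.0)

        amp_activity = (config.baseline_activity + calcium[:, t]) * artifact[:, t]
        bodies = _render_frame(
            config.image_shape, positions_activity[:, t], amp_activity, config.body_sigma_px
        )
        frame = (config.background + bodies) * bleach_activity[t]
        if config.noise_sigma_activity > 0:
            frame = frame + rng.normal(0, config.noise_sigma_activity, size=(H, W))
        activity_frames[t] = np.maximum(frame, 0.0)

    cell_class = [NEURON] * config.n_neurons + [NEMATOCYTE] * config.n_nematocytes
    truth = GroundTruth(
        positions_anchor=positions_anchor,
        positions_activity=positions_activity,
        spike_frames=spike_frames,
        cell_class=cell_class,
        region=region,
        calcium=calcium,
        artifact_factor=artifact,
        control_grid=grid,
        deformation_fields=deformation_fields,
    )
    anchor = Movie(anchor_frames, frame_rate_hz=config.frame_rate_hz, channel_name="anchor")
    activity = Movie(
        activity_frames, frame_rate_hz=config.frame_rate_hz, channel_name="activity"
    )
    return anchor, activity, truth


def fragment_tracks(
    truth: GroundTruth,
    gap_rate: float,
    gap_length: int,
    rng_seed: int = 0,
    n_gaps: int | None = None,
) -> tuple[list[Track], dict[int, int]]:
    """Split each ground-truth trajectory into tracklets separated by gaps.

    Gap starts are Bernoulli(``gap_rate``) per frame, or exactly ``n_gaps``
    randomly placed gaps per trajectory when given.  Returns the tracklets
    (all frames DETECTED) and a mapping tracklet_id -> true cell index.
    """
    if not 0 <= gap_rate <= 1:
        raise ValueError("gap_rate must be in [0, 1]")
    if gap_length < 1:
        raise ValueError("gap_length must be >= 1")
    rng = np.random.default_rng(rng_seed)
    T = truth.n_frames
    tracklets: list[Track] = []
    mapping: dict[int, int] = {}
    next_id = 0
    for cell in range(truth.n_cells):
        gap_starts: list[int] = []
        if gap_length < T - 2:
            if n_gaps is not None:
                candidates = np.arange(1, T - gap_length - 1)
                k = min(n_gaps, len(candidates))
                chosen = sorted(rng.choice(candidates, size=k, replace=False))
                prev_end = -1
                for g in chosen:
                    if g > prev_end:
                        gap_starts.append(int(g))
                        prev_end = g + gap_length
            else:
                t = 1
                while t < T - gap_length - 1:
                    if rng.random() < gap_rate:
                        gap_starts.append(t)
                        t += gap_length + 1
                    else:
                        t += 1
        segments = []
        start = 0
        for g in gap_starts:
            segments.append((start, g - 1))
            start = g + gap_length
        segments.append((start, T - 1))
        for seg_start, seg_end in segments:
            if seg_end < seg_start:
                continue
            length = seg_end - seg_start + 1
            tracklets.append(
                Track(
                    track_id=next_id,
                    start_frame=seg_start,
                    positions=truth.positions_anchor[cell, seg_start : seg_end + 1],
                    status=np.full(length, TrackStatus.DETECTED),
                )
            )
            mapping[next_id] = cell
            next_id += 1
    return tracklets, mapping
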