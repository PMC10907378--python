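"""Config-driven end-to-end orchestration and tracking evaluation.

Stage order: detect -> link -> stitch -> calcium-link -> signal processing ->
spike inference.  Every stage's outputs and the resolved configuration are
persisted to the run directory; a fixed seed makes runs reproducible.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import calcium as calcium_mod
from . import signals as signals_mod
from . import spikes as spikes_mod
from .detection import WaveletParams, detect_movie
from .io import (
    Movie,
    NeuronSignals,
    SpikeRaster,
    Track,
    read_movie,
    write_detections_csv,
    write_raster_csv,
    write_traces_csv,
    write_tracks_csv,
)
from .linking import LinkerParams, link_detections
from .simulate import GroundTruth, default_ar2_coefficients
from .stitching import StitchParams, stitch

__all__ = [
    "PipelineConfig",
    "PipelineStageError",
    "RunResult",
    "TrackingAccuracyReport",
    "run_pipeline",
    "evaluate_tracking",
    "save_raster_figure",
]

logger = logging.getLogger("trasein")

STAGES = ("detect", "link", "stitch", "calcium", "signals", "spikes")


class PipelineStageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """All pipeline parameters; defaults follow the published protocol."""

    anchor_path: str = ""
    activity_path: str = ""
    out_dir: str = "run"
    frame_rate_hz: float = 10.0
    rng_seed: int = 0
    stages: dict[str, bool] = field(
        default_factory=lambda: {s: True for s in STAGES}
    )
    detection_method: str = "wavelet"
    detection: WaveletParams = field(default_factory=WaveletParams)
    match_distance_d: float = 1.0
    tracker_method: str = "kalman_jv"
    tracker: LinkerParams = field(default_factory=LinkerParams)
    stitching: StitchParams = field(default_factory=StitchParams)
    calcium: calcium_mod.SubRoiParams = field(default_factory=calcium_mod.SubRoiParams)
    signals: signals_mod.SignalProcParams = field(
        default_factory=signals_mod.SignalProcParams
    )
    deconv: spikes_mod.DeconvParams = field(default_factory=spikes_mod.DeconvParams)
    cluster: spikes_mod.ClusterParams = field(default_factory=spikes_mod.ClusterParams)
    d_track: float = 3.0
    min_track_frames: int = 20
    keep_overrides: dict[int, bool] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "paths": {
                "anchor": self.anchor_path,
                "activity": self.activity_path,
                "out_dir": self.out_dir,
            },
            "frame_rate_hz": self.frame_rate_hz,
            "rng_seed": self.rng_seed,
            "stages": dict(self.stages),
            "detection": {
                "method": self.detection_method,
                "match_distance_d": self.match_distance_d,
                **dataclasses.asdict(self.detection),
            },
            "tracker": {
                "method": self.tracker_method,
                **dataclasses.asdict(self.tracker),
            },
            "stitch": dataclasses.asdict(self.stitching),
            "calcium": dataclasses.asdict(self.calcium),
            "signals": dataclasses.asdict(self.signals),
            "deconv": dataclasses.asdict(self.deconv),
            "cluster": dataclasses.asdict(self.cluster),
            "evaluation": {"d_track": self.d_track},
            "min_track_frames": self.min_track_frames,
            "keep_overrides": dict(self.keep_overrides),
        }

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        cfg = cls()
        paths = data.get("paths", {})
        cfg.anchor_path = paths.get("anchor", cfg.anchor_path)
        cfg.activity_path = paths.get("activity", cfg.activity_path)
        cfg.out_dir = paths.get("out_dir", cfg.out_dir)
        cfg.frame_rate_hz = data.get("frame_rate_hz", cfg.frame_rate_hz)
        cfg.rng_seed = data.get("rng_seed", cfg.rng_seed)
        cfg.stages.update(data.get("stages", {}))
        det = dict(data.get("detection", {}))
        cfg.detection_method = det.pop("method", cfg.detection_method)
        cfg.match_distance_d = det.pop("match_distance_d", cfg.match_distance_d)
        if det:
            cfg.detection = WaveletParams(**det)
        trk = dict(data.get("tracker", {}))
        cfg.tracker_method = trk.pop("method", cfg.tracker_method)
        if trk:
            cfg.tracker = LinkerParams(**trk)
        if "stitch" in data:
            cfg.stitching = StitchParams(**data["stitch"])
        if "calcium" in data:
            cfg.calcium = calcium_mod.SubRoiParams(**data["calcium"])
        if "signals" in data:
            cfg.signals = signals_mod.SignalProcParams(**data["signals"])
        if "deconv" in data:
            cfg.deconv = spikes_mod.DeconvParams(**data["deconv"])
        if "cluster" in data:
            cfg.cluster = spikes_mod.ClusterParams(**data["cluster"])
        cfg.d_track = data.get("evaluation", {}).get("d_track", cfg.d_track)
        cfg.min_track_frames = data.get("min_track_frames", cfg.min_track_frames)
        cfg.keep_overrides = {
            int(k): bool(v) for k, v in data.get("keep_overrides", {}).items()
        }
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


@dataclass
class RunResult:
    out_dir: Path
    tracklets: list[Track] = field(default_factory=list)
    tracks: list[Track] = field(default_factory=list)
    signals: list[NeuronSignals] = field(default_factory=list)
    classification: list = field(default_factory=list)
    raster: SpikeRaster | None = None


def run_pipeline(
    config: PipelineConfig,
    anchor: Movie | None = None,
    activity: Movie | None = None,
) -> RunResult:
    """Execute the enabled stages in order, persisting artifacts per stage.

    Movies may be passed in-memory (tests) or read from the configured paths.
    Raises :class:`PipelineStageError` naming the failed stage; partial
    outputs written before the failure are kept.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out_dir / "resolved_config.yaml")
    handler = logging.FileHandler(out_dir / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    result = RunResult(out_dir=out_dir)
    try:
        if anchor is None:
            anchor = read_movie(
                config.anchor_path, config.frame_rate_hz, channel_name="anchor"
            )
        if activity is None and (config.stages.get("calcium") or config.activity_path):
            activity = read_movie(
                config.activity_path, config.frame_rate_hz, channel_name="activity"
            )

        tracks: list[Track] = []
        if config.stages.get("detect", True):
            stage = "detect"
            logger.info("stage detect: %d frames", anchor.n_frames)
            try:
                detections = detect_movie(anchor.frames, config.detection)
            except Exception as exc:
                raise PipelineStageError(stage, exc) from exc
            write_detections_csv(detections, out_dir / "detections.csv")

            if config.stages.get("link", True):
                stage = "link"
                try:
                    result.tracklets = link_detections(detections, config.tracker)
                except Exception as exc:
                    raise PipelineStageError(stage, exc) from exc
                logger.info("stage link: %d tracklets", len(result.tracklets))
                write_tracks_csv(result.tracklets, out_dir / "tracklets.csv")

                if config.stages.get("stitch", True):
                    stage = "stitch"
                    try:
                        tracks = stitch(result.tracklets, config.stitching)
                    except Exception as exc:
                        raise PipelineStageError(stage, exc) from exc
                    logger.info("stage stitch: %d tracks", len(tracks))
                else:
                    tracks = result.tracklets
                write_tracks_csv(tracks, out_dir / "tracks.csv")
                with open(out_dir / "tracks_parents.json", "w") as fh:
                    json.dump(
                        {t.track_id: t.parent_tracklets for t in tracks}, fh, indent=1
                    )
                result.tracks = tracks

        if config.stages.get("calcium", True) and result.tracks and activity is not None:
            stage = "calcium"
            try:
                kept = [
                    t for t in result.tracks if t.n_frames >= config.min_track_frames
                ]
                result.signals = [
                    calcium_mod.extract_signals(t, anchor, activity, config.calcium)
                    for t in kept
                ]
            except Exception as exc:
                raise PipelineStageError(stage, exc) from exc
            logger.info("stage calcium: %d traces", len(result.signals))
            write_traces_csv(result.signals, out_dir / "traces.csv")

        processed: list[NeuronSignals] = []
        if config.stages.get("signals", True) and result.signals:
            stage = "signals"
            try:
                result.classification = signals_mod.classify_non_neuronal(
                    result.signals, config.signals, overrides=config.keep_overrides
                )
                review = pd.DataFrame(
                    [
                        {
                            "track_id": rec.track_id,
                            "p_value": rec.p_value,
                            "auto_flag": rec.keep_flag,
                            "user_override": rec.user_override,
                        }
                        for rec in result.classification
                    ]
                )
                review.to_csv(out_dir / "review.csv", index=False)
                keep_ids = {rec.track_id for rec in result.classification if rec.keep}
                for sig in result.signals:
                    if sig.track_id in keep_ids:
                        signals_mod.process_signals(sig, config.signals)
                        processed.append(sig)
            except Exception as exc:
                raise PipelineStageError(stage, exc) from exc
            logger.info("stage signals: %d kept", len(processed))
            write_traces_csv(result.signals, out_dir / "traces.csv")

        if config.stages.get("spikes", True) and processed:
            stage = "spikes"
            try:
                default_g = default_ar2_coefficients()
                events_by_neuron: dict[int, list[tuple[int, float]]] = {}
                for sig in processed:
                    trace = sig.calcium_smoothed[sig.span_mask]
                    trace = trace - np.median(trace)
                    params = config.deconv
                    if params.noise_sd is None:
                        # MAD of first differences: robust to the sparse
                        # transients that inflate PSD-based noise estimates
                        diffs = np.diff(trace)
                        mad = np.median(np.abs(diffs - np.median(diffs)))
                        params = dataclasses.replace(
                            params, noise_sd=float(mad / 0.6745 / np.sqrt(2))
                        )
                    if params.g1 is None:
                        # estimate the kernel before detrending/smoothing:
                        # both distort the autoregressive structure
                        pre = sig.calcium_ica[sig.span_mask]
                        try:
                            g1, g2, _ = spikes_mod.estimate_ar_params_robust(pre)
                        except ValueError:
                            g1, g2 = default_g
                        params = dataclasses.replace(params, g1=g1, g2=g2)
                    try:
                        _, s = spikes_mod.deconvolve(trace, params)
                    except ValueError:
                        events_by_neuron[sig.track_id] = []
                        continue
                    events = spikes_mod.cluster_spikes(s, config.cluster)
                    span_start = int(np.flatnonzero(sig.span_mask)[0])
                    events_by_neuron[sig.track_id] = [
                        (f + span_start, a) for f, a in events
                    ]
                raster = spikes_mod.build_raster(
                    events_by_neuron, n_frames=anchor.n_frames
                )
            except Exception as exc:
                raise PipelineStageError(stage, exc) from exc
            result.raster = raster
            write_raster_csv(raster, out_dir / "raster.csv")
            save_raster_figure(raster, out_dir / "raster.png")
            logger.info("stage spikes: %d events", len(raster.events))
        return result
    finally:
        logger.removeHandler(handler)
        handler.close()


def save_raster_figure(raster: SpikeRaster, path: str | Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ids = sorted({tid for tid, _, _ in raster.events})
    index = {tid: i for i, tid in enumerate(ids)}
    fig, ax = plt.subplots(figsize=(8, max(2, 0.1 * len(ids) + 1)))
    for tid, frame, amp in raster.events:
        ax.vlines(frame, index[tid] - 0.4, index[tid] + 0.4, color="k", lw=0.8)
    ax.set_xlabel("frame")
    ax.set_ylabel("neuron")
    ax.set_xlim(0, raster.n_frames)
    ax.set_ylim(-1, max(len(ids), 1))
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


# ---------------------------------------------------------------------------
# tracking evaluation


@dataclass
class TrackingAccuracyReport:
    """Per-ground-truth-trajectory tracking accuracy."""

    accuracies: np.ndarray  # (n_cells,) fraction in [0, 1]
    matched_track_ids: np.ndarray  # (n_cells,) best track id, -1 if none
    regions: list[str]

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.accuracies))

    @property
    def sem_accuracy(self) -> float:
        n = len(self.accuracies)
        return float(np.std(self.accuracies, ddof=1) / np.sqrt(n)) if n > 1 else 0.0

    def by_region(self) -> dict[str, float]:
        out = {}
        for region in ("foot", "body", "head"):
            mask = [r == region for r in self.regions]
            if any(mask):
                out[region] = float(np.mean(self.accuracies[np.array(mask)]))
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cell": np.arange(len(self.accuracies)),
                "region": self.regions,
                "track_id": self.matched_track_ids,
                "accuracy": self.accuracies,
            }
        )


def evaluate_tracking(
    tracks: list[Track], truth: GroundTruth, d_track: float = 3.0
) -> TrackingAccuracyReport:
    """Fraction of frames each true trajectory is correctly tracked.

    Each trajectory is paired with the track having maximal frame-wise
    agreement (within ``d_track`` px).  An identity switch — the paired track
    present but farther than ``d_track`` — invalidates all subsequent frames
    of that trajectory.
    """
    T = truth.n_frames
    n_cells = truth.n_cells
    accuracies = np.zeros(n_cells)
    matched = np.full(n_cells, -1)
    for cell in range(n_cells):
        traj = truth.positions_anchor[cell]
        best_track = None
        best_agreement = -1
        for track in tracks:
            lo = max(track.start_frame, 0)
            hi = min(track.end_frame, T - 1)
            if hi < lo:
                continue
            frames = np.arange(lo, hi + 1)
            d = np.linalg.norm(
                track.positions[lo - track.start_frame : hi - track.start_frame + 1]
                - traj[frames],
                axis=1,
            )
            agreement = int(np.sum(d <= d_track))
            if agreement > best_agreement:
                best_agreement = agreement
                best_track = track
        if best_track is None or best_agreement <= 0:
            continue
        matched[cell] = best_track.track_id
        correct = 0
        for t in range(T):
            if not best_track.covers(t):
                continue
            dist = float(np.linalg.norm(best_track.position_at(t) - traj[t]))
            if dist <= d_track:
                correct += 1
            else:
                break  # identity switch: subsequent frames count as incorrect
        accuracies[cell] = correct / T
    return TrackingAccuracyReport(
        accuracies=accuracies, matched_track_ids=matched, regions=list(truth.region)
    )
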