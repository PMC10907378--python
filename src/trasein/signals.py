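"""Trace-level signal processing: non-neuronal filtering, ICA artifact
removal, detrending, and smoothing.

Fixed stage order: raw -> ICA -> detrend -> smooth.  All stages preserve
trace length and the missing-frame (NaN) mask.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps
from scipy import stats
from sklearn.decomposition import FastICA
from sklearn.exceptions import ConvergenceWarning

from .io import NeuronSignals

__all__ = [
    "SignalProcParams",
    "ClassificationRecord",
    "classify_non_neuronal",
    "ica_motion_correct",
    "detrend",
    "smooth",
    "process_signals",
]


@dataclass(frozen=True)
class SignalProcParams:
    normality_p_threshold: float = 0.05
    ica_runs: int = 10
    ica_tolerance: float = 0.5
    butter_order: int = 5
    critical_period_frames: int = 100
    smooth_window_frames: int = 5
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.normality_p_threshold < 1:
            raise ValueError("normality_p_threshold must be in (0, 1)")
        if self.ica_runs < 1:
            raise ValueError("ica_runs must be >= 1")
        if self.butter_order < 1:
            raise ValueError("butter_order must be >= 1")
        if self.critical_period_frames <= 2 * self.smooth_window_frames:
            raise ValueError("critical_period must exceed 2 * smooth_window")
        if self.smooth_window_frames < 1 or self.smooth_window_frames % 2 != 1:
            raise ValueError("smooth_window_frames must be odd and >= 1")


@dataclass
class ClassificationRecord:
    track_id: int
    p_value: float
    keep_flag: bool
    user_override: bool | None = None

    @property
    def keep(self) -> bool:
        return self.keep_flag if self.user_override is None else self.user_override


def classify_non_neuronal(
    signals: list[NeuronSignals],
    params: SignalProcParams,
    overrides: dict[int, bool] | None = None,
) -> list[ClassificationRecord]:
    """Flag plateau/flat (nematocyte-like) cells via a normality test.

    Each mean-subtracted raw calcium trace is tested with the
    D'Agostino-Pearson omnibus test; a cell is kept iff normality is rejected
    (p < threshold) — spiking traces are heavy-tailed/skewed, plateau traces
    reduce to near-Gaussian imaging noise.  Zero-variance traces are flagged
    non-neuronal with p reported as 1.  ``overrides`` is a machine-readable
    allow/deny list standing in for an interactive review step.
    """
    overrides = overrides or {}
    records = []
    for sig in signals:
        values = sig.calcium_raw[sig.span_mask]
        if len(values) < 20:
            raise ValueError(
                f"track {sig.track_id}: need >= 20 samples for the normality test"
            )
        centered = values - values.mean()
        if np.allclose(centered, 0.0):
            p = 1.0
        else:
            _, p = stats.normaltest(centered)
            p = float(p)
        records.append(
            ClassificationRecord(
                track_id=sig.track_id,
                p_value=p,
                keep_flag=p < params.normality_p_threshold,
                user_override=overrides.get(sig.track_id),
            )
        )
    return records


def _standardize(x: np.ndarray) -> np.ndarray:
    return (x - x.mean()) / x.std()


def _corr(a: np.ndarray, b: np.ndarray) -> float:
    if a.std() == 0 or b.std() == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def ica_motion_correct(
    calcium_raw: np.ndarray, control: np.ndarray, params: SignalProcParams
) -> np.ndarray:
    """Remove shared-channel motion artifacts with two-signal ICA.

    Runs 2-component FastICA on the standardized (calcium, control) pair
    ``ica_runs`` times; per run the calcium component is the output with
    higher absolute correlation with the raw calcium, and across runs the one
    with minimal absolute correlation with the control wins.  The output is
    sign-fixed to correlate positively with the raw calcium and rescaled to
    its mean and variance.  Missing (NaN) frames are preserved.
    """
    calcium_raw = np.asarray(calcium_raw, dtype=float)
    control = np.asarray(control, dtype=float)
    if calcium_raw.shape != control.shape:
        raise ValueError("traces must have equal length")
    mask = ~np.isnan(calcium_raw)
    if not np.array_equal(mask, ~np.isnan(control)):
        raise ValueError("calcium and control must share the same missing mask")
    cal = calcium_raw[mask]
    ctrl = control[mask]
    mean, std = cal.mean(), cal.std()
    if ctrl.std() == 0 or std == 0:
        return calcium_raw.copy()

    X = np.column_stack([_standardize(cal), _standardize(ctrl)])
    rng = np.random.default_rng(params.rng_seed)
    best: tuple[float, np.ndarray] | None = None
    for _ in range(params.ica_runs):
        seed = int(rng.integers(0, 2**31 - 1))
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", ConvergenceWarning)
                ica = FastICA(
                    n_components=2,
                    tol=params.ica_tolerance,
                    random_state=seed,
                    max_iter=500,
                )
                S = ica.fit_transform(X)
        except Exception:
            continue
        comps = [S[:, 0], S[:, 1]]
        cal_corr = [abs(_corr(c, cal)) for c in comps]
        comp = comps[int(np.argmax(cal_corr))]
        ctrl_corr = abs(_corr(comp, ctrl))
        if best is None or ctrl_corr < best[0]:
            best = (ctrl_corr, comp)
    if best is None:
        warnings.warn("ICA failed to converge in all runs; returning raw calcium")
        return calcium_raw.copy()
    comp = best[1]
    if _corr(comp, cal) < 0:
        comp = -comp
    out = np.full_like(calcium_raw, np.nan)
    out[mask] = mean + std * _standardize(comp)
    return out


def detrend(trace: np.ndarray, params: SignalProcParams) -> np.ndarray:
    """Zero-phase high-pass Butterworth filter removing slow baseline drift.

    The cutoff is ``1/critical_period_frames`` cycles per frame; the filter is
    applied forward-backward so spike timing is not shifted.
    """
    trace = np.asarray(trace, dtype=float)
    mask = ~np.isnan(trace)
    values = trace[mask]
    min_len = 3 * (params.butter_order + 1) + 1
    if len(values) < min_len:
        raise ValueError(
            f"trace has {len(values)} valid frames; need >= {min_len} "
            f"for an order-{params.butter_order} zero-phase filter"
        )
    wn = 2.0 / params.critical_period_frames  # cutoff normalized by Nyquist
    b, a = sps.butter(params.butter_order, wn, btype="highpass")
    out = np.full_like(trace, np.nan)
    # mean removed up front (gust edge handling is poor with a DC offset);
    # Gustafsson's method avoids inflating transients near trace ends
    out[mask] = sps.filtfilt(b, a, values - values.mean(), method="gust")
    return out


def smooth(trace: np.ndarray, params: SignalProcParams) -> np.ndarray:
    """Centered moving average; edges use shrinking windows (no padding)."""
    trace = np.asarray(trace, dtype=float)
    w = params.smooth_window_frames
    mask = ~np.isnan(trace)
    values = trace[mask]
    if len(values) == 0:
        return trace.copy()
    kernel = np.ones(w)
    summed = np.convolve(values, kernel, mode="same")
    counts = np.convolve(np.ones_like(values), kernel, mode="same")
    out = np.full_like(trace, np.nan)
    out[mask] = summed / counts
    return out


def process_signals(sig: NeuronSignals, params: SignalProcParams) -> NeuronSignals:
    """Apply the fixed chain raw -> ICA -> detrend -> smooth in place."""
    sig.calcium_ica = ica_motion_correct(sig.calcium_raw, sig.control, params)
    sig.calcium_detrended = detrend(sig.calcium_ica, params)
    sig.calcium_smoothed = smooth(sig.calcium_detrended, params)
    return sig
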