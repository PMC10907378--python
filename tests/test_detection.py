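import itertools

import numpy as np
import pytest
from scipy.signal import convolve2d

from trasein.detection import (
    DetectionMetrics,
    WaveletParams,
    calibrate_wavelet,
    detect_wavelet,
    evaluate_detections,
    iuwt_decompose,
)
from trasein.io import FrameDetections

_B3 = np.array([1.0, 4.0, 6.0, 4.0, 1.0]) / 16.0


def _spots_frame(centers, amp=50.0, sigma=2.0, shape=(64, 64), noise=1.0, seed=0):
    rng = np.random.default_rng(seed)
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    frame = np.zeros(shape)
    for r0, c0 in centers:
        frame += amp * np.exp(-((rr - r0) ** 2 + (cc - c0) ** 2) / (2 * sigma**2))
    if noise > 0:
        frame += rng.normal(0, noise, shape)
    return frame


class TestIuwt:
    def test_constant_image(self):
        frame = np.full((32, 32), 7.5)
        planes, residual = iuwt_decompose(frame, 3)
        for plane in planes:
            np.testing.assert_allclose(plane, 0.0, atol=1e-12)
        np.testing.assert_allclose(residual, frame)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_reconstruction_identity(self, seed):
        frame = np.random.default_rng(seed).random((48, 40)) * 100
        planes, residual = iuwt_decompose(frame, 4)
        recon = sum(planes) + residual
        np.testing.assert_allclose(recon, frame, rtol=1e-9)

    def test_impulse_matches_direct_convolution(self):
        # oracle: direct separable convolution with the zero-stuffed B3 kernel
        n = 65
        frame = np.zeros((n, n))
        frame[n // 2, n // 2] = 1.0
        planes, _ = iuwt_decompose(frame, 3)
        current = frame
        for j in range(1, 4):
            spacing = 2 ** (j - 1)
            k1d = np.zeros(4 * spacing + 1)
            k1d[::spacing] = _B3
            kernel2d = np.outer(k1d, k1d)
            smoothed = convolve2d(current, kernel2d, mode="same", boundary="symm")
            expected_plane = current - smoothed
            # impulse is far from the border: boundary handling is irrelevant
            np.testing.assert_allclose(planes[j - 1], expected_plane, atol=1e-10)
            current = smoothed

    def test_too_small_image(self):
        with pytest.raises(ValueError, match="at most"):
            iuwt_decompose(np.zeros((8, 8)), 3)


class TestDetectWavelet:
    def test_all_zero_frame(self):
        det = detect_wavelet(np.zeros((32, 32)), WaveletParams(scale=2, k_sigma=3))
        assert len(det) == 0

    def test_three_spots_localized(self):
        centers = [(15.0, 15.0), (15.0, 48.0), (48.0, 30.0)]
        frame = _spots_frame(centers, amp=50.0, sigma=2.0, noise=1.0, seed=4)
        det = detect_wavelet(frame, WaveletParams(scale=2, k_sigma=3.0))
        assert len(det) == 3
        for r0, c0 in centers:
            d = np.linalg.norm(det.centroids - (r0, c0), axis=1).min()
            assert d < 1.0

    def test_min_area_filter(self):
        # a 2x2 bright block gives exactly 4 supra-threshold pixels at scale 1
        rng = np.random.default_rng(0)
        frame = np.abs(rng.normal(0, 0.01, (32, 32)))
        frame[15:17, 15:17] = 1000.0
        keep4 = detect_wavelet(frame, WaveletParams(scale=1, k_sigma=5.0, min_area_px=4))
        drop5 = detect_wavelet(frame, WaveletParams(scale=1, k_sigma=5.0, min_area_px=5))
        assert any(a == 4 for a in keep4.areas)
        assert len(drop5) == len(keep4) - 1

    def test_k_sigma_monotonicity(self):
        frame = _spots_frame([(20, 20), (20, 44), (44, 32)], noise=1.0, seed=7)
        counts = [
            len(detect_wavelet(frame, WaveletParams(scale=2, k_sigma=k)))
            for k in (1.0, 2.0, 3.0, 5.0, 8.0)
        ]
        assert counts == sorted(counts, reverse=True)


def _brute_force_metrics(pred, truth, d):
    """Enumerate all one-to-one matchings; maximize tp, then minimize distance."""
    pred = np.asarray(pred, dtype=float).reshape(-1, 2)
    truth = np.asarray(truth, dtype=float).reshape(-1, 2)
    best_tp, best_cost = 0, np.inf
    k = min(len(pred), len(truth))
    for size in range(k, -1, -1):
        for p_idx in itertools.combinations(range(len(pred)), size):
            for t_perm in itertools.permutations(range(len(truth)), size):
                dists = [
                    np.linalg.norm(pred[i] - truth[j])
                    for i, j in zip(p_idx, t_perm)
                ]
                if all(x < d for x in dists):
                    if size > best_tp or (size == best_tp and sum(dists) < best_cost):
                        best_tp = size
                        best_cost = sum(dists)
        if best_tp == size:
            break
    return best_tp


class TestEvaluateDetections:
    def test_perfect(self):
        pts = np.array([[1.0, 2.0], [5.0, 5.0], [9.0, 1.0]])
        det = FrameDetections(0, pts, np.full(3, 5))
        m = evaluate_detections(det, det, d=1.0)
        assert m.precision == m.recall == m.f1 == 1.0

    def test_reference_confusion_counts(self):
        m = DetectionMetrics.from_counts(tp=2171, fp=576, fn=1112)
        assert m.n_pred == 2747
        assert m.n_true == 3283
        assert round(100 * m.f1, 1) == 72.0

    def test_greedy_vs_optimal(self):
        # greedy would match pred0 to truth0 (dist 0.5), stranding pred1
        pred = np.array([[0.0, 0.5], [0.0, 1.5]])
        truth = np.array([[0.0, 1.0], [0.0, 2.2]])
        d = 1.0
        m = evaluate_detections(
            FrameDetections(0, pred, np.full(2, 5)),
            FrameDetections(0, truth, np.full(2, 5)),
            d,
        )
        assert m.tp == _brute_force_metrics(pred, truth, d) == 2

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_exhaustive_oracle(self, seed):
        rng = np.random.default_rng(seed)
        pred = rng.random((4, 2)) * 6
        truth = rng.random((4, 2)) * 6
        d = 2.0
        m = evaluate_detections(
            FrameDetections(0, pred, np.full(len(pred), 5)),
            FrameDetections(0, truth, np.full(len(truth), 5)),
            d,
        )
        assert m.tp == _brute_force_metrics(pred, truth, d)

    def test_symmetry(self):
        rng = np.random.default_rng(3)
        a = rng.random((5, 2)) * 10
        b = rng.random((3, 2)) * 10
        da = FrameDetections(0, a, np.full(5, 5))
        db = FrameDetections(0, b, np.full(3, 5))
        m1 = evaluate_detections(da, db, d=3.0)
        m2 = evaluate_detections(db, da, d=3.0)
        assert m1.tp == m2.tp
        assert m1.precision == m2.recall
        assert m1.recall == m2.precision

    def test_empty_pred(self):
        truth = FrameDetections(0, np.array([[1.0, 1.0]]), np.array([5]))
        empty = FrameDetections(0, np.empty((0, 2)), np.empty(0, dtype=int))
        m = evaluate_detections(empty, truth, d=1.0)
        assert m.precision == 0.0
        assert m.recall == 0.0


class TestCalibrateWavelet:
    @pytest.fixture()
    def training_image(self):
        centers = [(12.0, 12.0), (12.0, 40.0), (40.0, 12.0), (40.0, 40.0), (26.0, 26.0)]
        frame = _spots_frame(centers, amp=40.0, sigma=2.0, noise=2.0, seed=1)
        truth = FrameDetections(0, np.array(centers), np.full(5, 5))
        return frame, truth

    def test_single_point(self, training_image):
        params = calibrate_wavelet([training_image], [3], [2.5], d=2.0)
        assert params == WaveletParams(scale=3, k_sigma=2.5)

    def test_matches_exhaustive(self, training_image):
        frame, truth = training_image
        scales, ks = [1, 2], [2.0, 4.0]
        best = calibrate_wavelet([training_image], scales, ks, d=2.0)
        f1s = {
            (s, k): evaluate_detections(
                detect_wavelet(frame, WaveletParams(scale=s, k_sigma=k)), truth, 2.0
            ).f1
            for s in scales
            for k in ks
        }
        expected = min(f1s, key=lambda sk: (-f1s[sk], sk[0], sk[1]))
        assert (best.scale, best.k_sigma) == expected

    def test_tie_break_smaller_scale(self):
        # frame detected perfectly at every grid point -> tie on f1 = 1
        centers = [(16.0, 16.0), (16.0, 48.0), (48.0, 32.0)]
        frame = _spots_frame(centers, amp=100.0, sigma=2.0, noise=0.5, seed=2)
        truth = FrameDetections(0, np.array(centers), np.full(3, 5))
        params = calibrate_wavelet([(frame, truth)], [2, 3], [3.0, 4.0], d=2.0)
        assert params.scale == 2
        assert params.k_sigma == 3.0

    def test_empty_grid(self, training_image):
        with pytest.raises(ValueError):
            calibrate_wavelet([training_image], [], [3.0], d=2.0)


class TestCalibratedAccuracy:
    def test_f1_at_snr5(self):
        # well-separated spots, SNR = amp/noise = 5
        rng = np.random.default_rng(0)
        centers = [
            (r, c)
            for r in np.linspace(10, 86, 5)
            for c in np.linspace(10, 86, 5)
        ]
        jitter = rng.uniform(-2, 2, (len(centers), 2))
        centers = np.array(centers) + jitter
        frame = _spots_frame(centers, amp=10.0, sigma=2.0, shape=(96, 96), noise=2.0, seed=5)
        truth = FrameDetections(0, centers, np.full(len(centers), 5))
        params = calibrate_wavelet(
            [(frame, truth)], [1, 2, 3], [1.5, 2.0, 3.0, 4.0], d=2.0
        )
        test_frame = _spots_frame(centers, amp=10.0, sigma=2.0, shape=(96, 96), noise=2.0, seed=6)
        m = evaluate_detections(detect_wavelet(test_frame, params), truth, d=2.0)
        assert m.f1 >= 0.95
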