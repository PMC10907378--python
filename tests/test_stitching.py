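import itertools

import numpy as np
import pytest

from trasein.io import Track, TrackStatus
from trasein.simulate import SimConfig, fragment_tracks, simulate_movie
from trasein.stitching import (
    StitchParams,
    build_stitch_costs,
    propagate_backward,
    propagate_forward,
    stitch,
    tps_fit,
)
from trasein.tps import DegenerateControlPointsError


def _track(track_id, start, positions):
    positions = np.asarray(positions, dtype=float).reshape(-1, 2)
    return Track(
        track_id=track_id,
        start_frame=start,
        positions=positions,
        status=np.full(len(positions), int(TrackStatus.DETECTED)),
    )


def _translating_population(n=8, T=30, velocity=(1.0, 0.0), seed=0):
    rng = np.random.default_rng(seed)
    starts = rng.uniform(10, 60, (n, 2))
    v = np.asarray(velocity)
    return [
        _track(i, 0, starts[i] + np.outer(np.arange(T), v)) for i in range(n)
    ]


class TestTpsFit:
    def test_identity(self, rng):
        pts = rng.random((10, 2)) * 50
        warp = tps_fit(pts, pts, alpha=10.0)
        np.testing.assert_allclose(warp(pts), pts, atol=1e-8)
        probe = rng.random((5, 2)) * 50
        np.testing.assert_allclose(warp(probe), probe, atol=1e-8)

    @pytest.mark.parametrize("alpha", [0.0, 1.0, 10.0, 100.0])
    def test_translation_exact_for_all_alpha(self, alpha, rng):
        pts = rng.random((8, 2)) * 40
        t = np.array([3.5, -2.0])
        warp = tps_fit(pts, pts + t, alpha=alpha)
        probe = rng.random((6, 2)) * 40
        np.testing.assert_allclose(warp(probe), probe + t, atol=1e-8)

    def test_affine_exact(self, rng):
        pts = rng.random((12, 2)) * 30
        A = np.array([[1.1, 0.2], [-0.1, 0.95]])
        t = np.array([2.0, 1.0])
        warp = tps_fit(pts, pts @ A.T + t, alpha=5.0)
        probe = rng.random((5, 2)) * 30
        np.testing.assert_allclose(warp(probe), probe @ A.T + t, atol=1e-7)

    def test_quadratic_warp_heldout(self, rng):
        def true_warp(p):
            out = p.copy()
            out[:, 0] = p[:, 0] + 0.002 * (p[:, 1] - 25) ** 2
            out[:, 1] = p[:, 1] + 0.001 * (p[:, 0] - 25) ** 2
            return out

        control = rng.random((30, 2)) * 50
        warp = tps_fit(control, true_warp(control), alpha=0.0)
        heldout = rng.random((20, 2)) * 40 + 5
        err = np.linalg.norm(warp(heldout) - true_warp(heldout), axis=1)
        assert err.max() < 0.1

    def test_degenerate_points(self):
        line = np.column_stack([np.arange(6, dtype=float), np.arange(6, dtype=float)])
        with pytest.raises(DegenerateControlPointsError, match="affine"):
            tps_fit(line, line + 1.0, alpha=1.0)


class TestPropagation:
    def test_stationary_neighbors(self):
        tracklets = [
            _track(i, 0, np.tile((10.0 * i + 5, 20.0 + 6.0 * (i % 3)), (30, 1)))
            for i in range(5)
        ]
        target = _track(99, 0, np.tile((25.0, 20.0), (10, 1)))
        est = propagate_forward(target, tracklets + [target], StitchParams(), 10)
        for t in range(9, 20):
            np.testing.assert_allclose(est[t], (25.0, 20.0), atol=1e-6)

    def test_translation_advances(self):
        tracklets = _translating_population(n=6, T=30)
        target = _track(99, 0, tracklets[0].positions[:10] + (3.0, 3.0))
        est = propagate_forward(target, tracklets + [target], StitchParams(), 10)
        base = target.positions[-1]
        for k in range(1, 11):
            np.testing.assert_allclose(est[9 + k], base + (k, 0.0), atol=1e-6)

    def test_backward_translation(self):
        tracklets = _translating_population(n=6, T=30)
        target = _track(99, 15, tracklets[0].positions[15:] + (3.0, 3.0))
        est = propagate_backward(target, tracklets + [target], StitchParams(), 10)
        base = target.positions[0]
        for k in range(1, 11):
            np.testing.assert_allclose(est[15 - k], base - (k, 0.0), atol=1e-6)

    def test_truncation_without_neighbors(self):
        lone = _track(0, 0, np.tile((5.0, 5.0), (10, 1)))
        est = propagate_forward(lone, [lone], StitchParams(), 10)
        assert set(est) == {9}  # only the terminus itself

    def test_across_gap_on_deformed_movie(self):
        config = SimConfig(
            n_neurons=25,
            n_nematocytes=0,
            image_shape=(96, 128),
            n_frames=60,
            rng_seed=5,
            deformation_amplitude_px=3.0,
        )
        _, _, truth = simulate_movie(config)
        tracklets, mapping = fragment_tracks(truth, 0.0, 1, rng_seed=0)
        # hide frames 25..34 of cell 0 and propagate across the gap
        cell = 0
        full = truth.positions_anchor[cell]
        head = _track(100, 0, full[:25])
        others = [t for t in tracklets if mapping[t.track_id] != cell]
        est = propagate_forward(head, others + [head], StitchParams(), 10)
        assert 34 in est
        err = np.linalg.norm(est[34] - full[34])
        assert err < 1.0


class TestStitchCosts:
    def test_split_stationary_cost_zero(self):
        pop = [
            _track(i, 0, np.tile((10.0 + 7 * i, 30.0 + 5.0 * (i % 3)), (40, 1)))
            for i in range(5)
        ]
        a = _track(50, 0, np.tile((25.0, 50.0), (15, 1)))
        b = _track(51, 25, np.tile((25.0, 50.0), (15, 1)))
        cm = build_stitch_costs(pop + [a, b], StitchParams())
        i, j = 5, 6
        assert cm.costs[i, j] < 1e-6

    def test_overlapping_forbidden(self):
        a = _track(0, 0, np.tile((5.0, 5.0), (20, 1)))
        b = _track(1, 10, np.tile((6.0, 6.0), (20, 1)))
        cm = build_stitch_costs([a, b], StitchParams())
        assert np.isinf(cm.costs[0, 1])
        assert np.isinf(cm.costs[1, 0])
        assert np.all(np.isinf(np.diag(cm.costs)))

    def test_hand_computed_translation_cost(self):
        # all tracklets translate (0, 1) px/frame; tracklet b resumes offset
        # by 2 rows, so forward and backward estimates stay 2 px apart
        pop = _translating_population(n=6, T=30, velocity=(0.0, 1.0), seed=3)
        a = _track(50, 0, np.array([[20.0, 10.0 + t] for t in range(6)]))  # ends f5
        b_start = np.array([22.0, 10.0 + 9.0])
        b = _track(51, 9, b_start + np.outer(np.arange(6), (0.0, 1.0)))
        cm = build_stitch_costs(pop + [a, b], StitchParams())
        np.testing.assert_allclose(cm.costs[6, 7], 2.0, atol=1e-6)


class TestStitch:
    def test_far_apart_unmerged(self):
        pop = [
            _track(i, 0, np.tile((10.0 + 7 * i, 10.0), (40, 1))) for i in range(4)
        ]
        a = _track(50, 0, np.tile((40.0, 60.0), (15, 1)))
        b = _track(51, 25, np.tile((60.0, 80.0), (15, 1)))  # ~28 px away > eta
        tracks = stitch(pop + [a, b], StitchParams(eta_px=5.0))
        assert len(tracks) == 6

    def test_split_restored(self):
        config = SimConfig(
            n_neurons=25,
            n_nematocytes=0,
            image_shape=(96, 128),
            n_frames=80,
            rng_seed=6,
            deformation_amplitude_px=3.0,
        )
        _, _, truth = simulate_movie(config)
        tracklets, mapping = fragment_tracks(
            truth, 0.0, 10, rng_seed=1, n_gaps=1
        )
        tracks = stitch(tracklets, StitchParams(alpha=10.0, eta_px=5.0))
        restored = 0
        for track in tracks:
            cells = {mapping[pid] for pid in track.parent_tracklets}
            if len(track.parent_tracklets) == 2 and len(cells) == 1:
                restored += 1
        assert restored >= 0.95 * config.n_cells
        # conservation: gap frames INTERPOLATED, detected count preserved
        n_detected = sum(
            int(np.sum(t.status == int(TrackStatus.DETECTED))) for t in tracks
        )
        assert n_detected == sum(t.n_frames for t in tracklets)
        assert len(tracks) <= len(tracklets)

    def test_no_temporal_overlap_links(self):
        pop = _translating_population(n=10, T=25, seed=8)
        pieces = []
        next_id = 0
        for track in pop:
            pieces.append(_track(next_id, 0, track.positions[:12]))
            next_id += 1
            pieces.append(_track(next_id, 14, track.positions[14:]))
            next_id += 1
        tracks = stitch(pieces, StitchParams())
        for track in tracks:
            spans = []
            for pid in track.parent_tracklets:
                src = next(p for p in pieces if p.track_id == pid)
                spans.append((src.start_frame, src.end_frame))
            spans.sort()
            for (s1, e1), (s2, e2) in zip(spans[:-1], spans[1:]):
                assert s2 > e1

    def _brute_force_total(self, costs, eta):
        """Minimum of sum(link costs) + eta * n_chains over all matchings."""
        n = len(costs)
        finite = [
            (i, j) for i in range(n) for j in range(n) if np.isfinite(costs[i, j])
        ]
        best = eta * n  # no links at all
        for k in range(1, len(finite) + 1):
            for subset in itertools.combinations(finite, k):
                rows = [i for i, _ in subset]
                cols = [j for _, j in subset]
                if len(set(rows)) < k or len(set(cols)) < k:
                    continue
                total = sum(costs[i, j] for i, j in subset) + eta * (n - k)
                best = min(best, total)
        return best

    def _achieved_total(self, tracks, costs, pieces, eta):
        id_to_idx = {p.track_id: k for k, p in enumerate(pieces)}
        total = 0.0
        n_links = 0
        for track in tracks:
            chain = [id_to_idx[pid] for pid in track.parent_tracklets]
            for a, b in zip(chain[:-1], chain[1:]):
                total += costs[a, b]
                n_links += 1
        return total + eta * (len(pieces) - n_links)

    @pytest.mark.parametrize("n_pieces,seed", [(4, 0), (6, 1), (6, 2)])
    def test_assignment_optimality(self, n_pieces, seed):
        rng = np.random.default_rng(seed)
        pop = _translating_population(n=6, T=40, seed=seed + 10)
        pieces = []
        next_id = 100
        for k in range(n_pieces):
            start = int(rng.integers(0, 25))
            length = int(rng.integers(5, 12))
            origin = rng.uniform(15, 55, 2)
            pieces.append(
                _track(
                    next_id,
                    start,
                    origin + np.outer(np.arange(length), (1.0, 0.0)),
                )
            )
            next_id += 1
        params = StitchParams(eta_px=5.0)
        costs = build_stitch_costs(pop + pieces, params).costs
        sub = costs[len(pop) :, len(pop) :]
        # population tracklets span all frames: only pieces can link
        tracks = stitch(pop + pieces, params)
        achieved = self._achieved_total(
            [t for t in tracks if set(t.parent_tracklets) <= {p.track_id for p in pieces}],
            sub,
            pieces,
            params.eta_px,
        )
        expected = self._brute_force_total(sub, params.eta_px)
        assert achieved == pytest.approx(expected, abs=1e-9)

    def test_eta_monotonicity(self):
        pop = _translating_population(n=6, T=40, seed=4)
        pieces = []
        next_id = 100
        for k in range(4):
            origin = np.array([20.0 + 8 * k, 10.0])
            pieces.append(_track(next_id, 0, origin + np.outer(np.arange(10), (1.0, 0.0))))
            next_id += 1
            resume = origin + np.array([0.0, (k + 1) * 1.2]) + np.outer([15], (1.0, 0.0))[0]
            pieces.append(
                _track(next_id, 15, resume + np.outer(np.arange(10), (1.0, 0.0)))
            )
            next_id += 1
        counts = []
        for eta in (1e-9, 0.5, 1.5, 3.0, 10.0):
            tracks = stitch(pop + pieces, StitchParams(eta_px=eta))
            n_links = sum(len(t.parent_tracklets) - 1 for t in tracks)
            counts.append(n_links)
        assert counts[0] == 0
        assert counts == sorted(counts)

    def test_gap_frames_interpolated(self):
        pop = _translating_population(n=6, T=40, seed=7)
        a = _track(50, 0, pop[0].positions[:12] + (2.0, 2.0))
        b = _track(51, 18, pop[0].positions[18:30] + (2.0, 2.0))
        tracks = stitch(pop + [a, b], StitchParams())
        merged = next(t for t in tracks if len(t.parent_tracklets) == 2)
        assert merged.start_frame == 0
        assert merged.end_frame == 29
        gap_status = [merged.status_at(t) for t in range(12, 18)]
        assert all(s == int(TrackStatus.INTERPOLATED) for s in gap_status)
        # interpolated positions follow the true translated trajectory
        for t in range(12, 18):
            true_pos = pop[0].positions[t] + (2.0, 2.0)
            assert np.linalg.norm(merged.position_at(t) - true_pos) < 0.5
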