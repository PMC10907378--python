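"""Smoothed thin-plate-spline 2-D deformation maps.

The map minimizes squared residuals at the control points plus
``alpha`` times the bending energy.  Because the polynomial part is an
unpenalized affine term, any affine relation between source and target
points is reproduced exactly for every ``alpha``.
"""

from __future__ import annotations

import numpy as np

__all__ = ["ThinPlateSpline", "DegenerateControlPointsError"]


class DegenerateControlPointsError(ValueError):
    """Control points are collinear or coincident; consider an affine fit."""


def _tps_kernel(r2: np.ndarray) -> np.ndarray:
    # U(r) = r^2 log r = 0.5 * r^2 log r^2, with U(0) = 0
    out = np.zeros_like(r2)
    mask = r2 > 0
    out[mask] = 0.5 * r2[mask] * np.log(r2[mask])
    return out


class ThinPlateSpline:
    """A fitted 2-D -> 2-D thin-plate-spline map.

    Parameters
    ----------
    source, target:
        ``(n, 2)`` arrays of corresponding control points.
    alpha:
        Smoothness (bending-energy weight); ``alpha = 0`` interpolates.
    """

    def __init__(self, source: np.ndarray, target: np.ndarray, alpha: float = 0.0):
        source = np.asarray(source, dtype=np.float64).reshape(-1, 2)
        target = np.asarray(target, dtype=np.float64).reshape(-1, 2)
        if source.shape != target.shape:
            raise ValueError("source and target must have matching shapes")
        n = len(source)
        if n < 3:
            raise DegenerateControlPointsError(
                f"need at least 3 control points, got {n}"
            )
        if alpha < 0:
            raise ValueError("alpha must be >= 0")

        # collinearity check on the affine design matrix
        centered = source - source.mean(axis=0)
        if np.linalg.matrix_rank(centered, tol=1e-9 * max(1.0, np.abs(centered).max())) < 2:
            raise DegenerateControlPointsError(
                "control points are collinear or coincident; fall back to an affine fit"
            )

        diff = source[:, None, :] - source[None, :, :]
        K = _tps_kernel(np.sum(diff**2, axis=-1))
        P = np.column_stack([np.ones(n), source])
        A = np.zeros((n + 3, n + 3))
        A[:n, :n] = K + alpha * np.eye(n)
        A[:n, n:] = P
        A[n:, :n] = P.T
        b = np.zeros((n + 3, 2))
        b[:n] = target
        try:
            sol = np.linalg.solve(A, b)
        except np.linalg.LinAlgError as exc:  # pragma: no cover - rank guarded above
            raise DegenerateControlPointsError(str(exc)) from exc
        self._source = source
        self._w = sol[:n]
        self._affine = sol[n:]
        self.alpha = float(alpha)

    def __call__(self, points: np.ndarray) -> np.ndarray:
        points = np.asarray(points, dtype=np.float64)
        single = points.ndim == 1
        pts = points.reshape(-1, 2)
        diff = pts[:, None, :] - self._source[None, :, :]
        U = _tps_kernel(np.sum(diff**2, axis=-1))
        out = (
            U @ self._w
            + np.column_stack([np.ones(len(pts)), pts]) @ self._affine
        )
        return out[0] if single else out
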