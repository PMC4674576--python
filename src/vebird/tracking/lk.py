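"""Sparse pyramidal Lucas-Kanade point tracking.

Iterative translational LK over a Gaussian image pyramid, vectorized across
points (one ``map_coordinates`` call per iteration for all point windows).
"""

from __future__ import annotations

import numpy as np
from scipy.ndimage import gaussian_filter, map_coordinates

__all__ = ["lk_track"]


def _pyramid(img: np.ndarray, levels: int) -> list[np.ndarray]:
    pyr = [np.ascontiguousarray(img, dtype=np.float32)]
    for _ in range(levels - 1):
        sm = gaussian_filter(pyr[-1], 1.0)
        pyr.append(sm[::2, ::2])
    return pyr


def lk_track(
    prev: np.ndarray,
    curr: np.ndarray,
    points: np.ndarray,
    half_win: int = 4,
    levels: int = 2,
    iters: int = 10,
    eps: float = 0.01,
) -> tuple[np.ndarray, np.ndarray]:
    """Track ``points`` (``(n, 2)`` float x,y) from ``prev`` to ``curr``.

    Returns ``(new_points, status)``; failed points (window off-frame or
    rank-deficient gradient matrix) keep their input position with
    ``status=False``.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=np.float64))
    n = pts.shape[0]
    if n == 0:
        return pts.copy(), np.zeros(0, dtype=bool)
    prev_pyr = _pyramid(prev, levels)
    curr_pyr = _pyramid(curr, levels)

    offs = np.arange(-half_win, half_win + 1, dtype=np.float64)
    oy, ox = np.meshgrid(offs, offs, indexing="ij")
    ox = ox.ravel()[None, :]  # (1, w2)
    oy = oy.ravel()[None, :]

    status = np.ones(n, dtype=bool)
    g = np.zeros((n, 2))  # flow at current level, (dx, dy)

    for level in range(levels - 1, -1, -1):
        p_prev = prev_pyr[level]
        p_curr = curr_pyr[level]
        h, w = p_prev.shape
        scale = 2.0**level
        pl = pts / scale
        gy_img, gx_img = np.gradient(p_prev)

        base_x = pl[:, 0:1] + ox
        base_y = pl[:, 1:2] + oy
        in_prev = (
            (pl[:, 0] >= half_win)
            & (pl[:, 0] <= w - 1 - half_win)
            & (pl[:, 1] >= half_win)
            & (pl[:, 1] <= h - 1 - half_win)
        )
        status &= in_prev
        coords = np.stack([base_y.ravel(), base_x.ravel()])
        t_win = map_coordinates(p_prev, coords, order=1, mode="nearest").reshape(n, -1)
        ix = map_coordinates(gx_img, coords, order=1, mode="nearest").reshape(n, -1)
        iy = map_coordinates(gy_img, coords, order=1, mode="nearest").reshape(n, -1)

        gxx = (ix * ix).sum(axis=1)
        gxy = (ix * iy).sum(axis=1)
        gyy = (iy * iy).sum(axis=1)
        det = gxx * gyy - gxy * gxy
        solvable = det > 1e-9
        status &= solvable
        det = np.where(solvable, det, 1.0)

        for _ in range(iters):
            cx = base_x + g[:, 0:1]
            cy = base_y + g[:, 1:2]
            i_win = map_coordinates(
                p_curr, np.stack([cy.ravel(), cx.ravel()]), order=1, mode="nearest"
            ).reshape(n, -1)
            diff = t_win - i_win
            bx = (diff * ix).sum(axis=1)
            by = (diff * iy).sum(axis=1)
            vx = (gyy * bx - gxy * by) / det
            vy = (gxx * by - gxy * bx) / det
            upd = np.stack([vx, vy], axis=1)
            upd[~status] = 0.0
            g += upd
            if np.abs(upd).max(initial=0.0) < eps:
                break

        # points tracked outside the current frame fail
        tx = pl[:, 0] + g[:, 0]
        ty = pl[:, 1] + g[:, 1]
        status &= (tx >= 0) & (tx <= w - 1) & (ty >= 0) & (ty <= h - 1)
        if level > 0:
            g *= 2.0

    new_pts = pts + g
    new_pts[~status] = pts[~status]
    return new_pts, status
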