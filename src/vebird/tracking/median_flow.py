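"""Median Flow frame-to-frame tracker with forward-backward error filtering.

A grid of points inside the bounding box is tracked forward with pyramidal
Lucas-Kanade, then tracked backward from the predicted positions; a point's
forward-backward (FB) error is the distance between its original position and
the backward-tracked one.  Points with above-median FB error or below-median
patch correlation are discarded, and the box is translated by the median
displacement and rescaled by the median pairwise-distance ratio of the
surviving points.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import map_coordinates

from ..geometry import BoundingBox
from .lk import lk_track

__all__ = ["MedianFlowResult", "median_flow"]


@dataclass(frozen=True)
class MedianFlowResult:
    """Outcome of one Median Flow step, with the per-point tracking state."""

    box: BoundingBox | None
    median_fb_error: float
    n_points: int  # surviving points
    points: np.ndarray | None = None  # initial grid, (n, 2)
    forward_points: np.ndarray | None = None  # LK predictions, (n, 2)
    fb_errors: np.ndarray | None = None  # forward-backward error per point
    valid: np.ndarray | None = None  # surviving-point mask


def _point_grid(box: BoundingBox, n: int = 10, margin: float = 0.1) -> np.ndarray:
    fx = np.linspace(margin, 1.0 - margin, n)
    gx, gy = np.meshgrid(box.x + fx * box.w, box.y + fx * box.h, indexing="xy")
    return np.stack([gx.ravel(), gy.ravel()], axis=1)


def _patch_ncc(img0, img1, pts0, pts1, half: int = 2) -> np.ndarray:
    offs = np.arange(-half, half + 1, dtype=float)
    oy, ox = np.meshgrid(offs, offs, indexing="ij")
    ox, oy = ox.ravel()[None, :], oy.ravel()[None, :]

    def windows(img, pts):
        cx = pts[:, 0:1] + ox
        cy = pts[:, 1:2] + oy
        vals = map_coordinates(
            img.astype(np.float32), np.stack([cy.ravel(), cx.ravel()]), order=1, mode="nearest"
        ).reshape(pts.shape[0], -1)
        return vals - vals.mean(axis=1, keepdims=True)

    w0 = windows(img0, pts0)
    w1 = windows(img1, pts1)
    denom = np.linalg.norm(w0, axis=1) * np.linalg.norm(w1, axis=1)
    denom = np.where(denom < 1e-9, 1.0, denom)
    return (w0 * w1).sum(axis=1) / denom


def median_flow(
    prev_frame: np.ndarray,
    frame: np.ndarray,
    box: BoundingBox,
    fb_threshold: float = 10.0,
    min_points: int = 5,
    grid_n: int = 10,
) -> MedianFlowResult:
    """One Median Flow step; ``box`` coordinates are pixels in ``prev_frame``."""
    h, w = prev_frame.shape[:2]
    if not (box.x >= 0 and box.y >= 0 and box.x2 <= w and box.y2 <= h):
        raise ValueError(f"box {box.as_tuple()} lies outside the {w}x{h} frame")

    pts = _point_grid(box, n=grid_n)
    fwd, st_f = lk_track(prev_frame, frame, pts)
    bwd, st_b = lk_track(frame, prev_frame, fwd)
    valid = st_f & st_b
    fb = np.hypot(*(pts - bwd).T)
    if valid.sum() < min_points:
        return MedianFlowResult(None, float("inf"), int(valid.sum()), pts, fwd, fb, valid)

    ncc = _patch_ncc(prev_frame, frame, pts, fwd)
    med_fb = float(np.median(fb[valid]))
    med_ncc = float(np.median(ncc[valid]))
    keep = valid & (fb <= med_fb) & (ncc >= med_ncc)
    if keep.sum() < min_points:
        return MedianFlowResult(None, med_fb, int(keep.sum()), pts, fwd, fb, keep)
    kept_fb = float(np.median(fb[keep]))
    if kept_fb > fb_threshold:
        return MedianFlowResult(None, kept_fb, int(keep.sum()), pts, fwd, fb, keep)

    disp = fwd[keep] - pts[keep]
    dx = float(np.median(disp[:, 0]))
    dy = float(np.median(disp[:, 1]))

    p0, p1 = pts[keep], fwd[keep]
    if p0.shape[0] >= 2:
        iu = np.triu_indices(p0.shape[0], 1)
        d0 = np.hypot(p0[iu[0], 0] - p0[iu[1], 0], p0[iu[0], 1] - p0[iu[1], 1])
        d1 = np.hypot(p1[iu[0], 0] - p1[iu[1], 0], p1[iu[0], 1] - p1[iu[1], 1])
        ok = d0 > 1e-9
        scale = float(np.median(d1[ok] / d0[ok])) if ok.any() else 1.0
    else:
        scale = 1.0

    new_w, new_h = box.w * scale, box.h * scale
    ncx, ncy = box.cx + dx, box.cy + dy
    new_box = BoundingBox(ncx - new_w / 2.0, ncy - new_h / 2.0, new_w, new_h)
    # a box drifting mostly off-frame is a tracking failure
    ix = min(new_box.x2, w) - max(new_box.x, 0)
    iy = min(new_box.y2, h) - max(new_box.y, 0)
    if ix < 0.5 * new_w or iy < 0.5 * new_h:
        return MedianFlowResult(None, kept_fb, int(keep.sum()), pts, fwd, fb, keep)
    return MedianFlowResult(new_box, kept_fb, int(keep.sum()), pts, fwd, fb, keep)
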