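"""Iris localization with a randomized Hough transform (RHT).

The detector samples minimal point groups from the edge image, solves each
group for a conic (5 points) or circle (3 points), and votes the resulting
parameters into five (or three) independent 1-D accumulators.  Two features
distinguish it from a plain RHT:

* **Distance-constrained sampling** — every pair of points in a sampled group
  must be at least ``min_pair_distance`` apart.  Nearby points (typically a
  contour point and an adjacent noise point) produce wildly wrong conics; the
  constraint suppresses those invalid votes, which is what makes the detector
  usable on heavily noisy edge images.
* **Circle-then-ellipse cascade** — circle detection (3-point groups, 3
  accumulators) is cheap, so it runs first; only if it fails (weak accumulator
  peak or low inlier support, e.g. because the iris is foreshortened into an
  ellipse) does the 5-parameter ellipse detector run.

Accumulator peaks are quantized to bin centers, so the winning hypothesis is
refined by a least-squares fit over its inlier points before being returned.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import feature as skfeature

from .geometry import (
    Circle,
    ConicParams,
    Ellipse,
    fit_circle_lstsq,
    fit_circles_batch,
    fit_conic_lstsq,
    fit_conics_batch,
)

__all__ = [
    "RhtConfig",
    "EdgeConfig",
    "preprocess_frame",
    "sample_group",
    "sample_groups",
    "detect_ellipse_rht",
    "detect_circle_rht",
    "detect_eye",
    "DetectionResult",
    "detection_correct",
]


@dataclass(frozen=True)
class EdgeConfig:
    """Edge extraction: grayscale -> Canny -> small-component removal.

    An image that is already a sparse binary mask (at most two gray levels,
    minority foreground) is taken as an edge map directly.  Denoising dilates
    the edge mask by ``bridge_px`` (connecting dotted contours across small
    gaps), labels the dilated mask, and drops components containing fewer
    than ``min_component`` original edge pixels — scattered noise points are
    removed while fragmented contours survive.
    """

    canny_sigma: float = 1.4
    canny_low: float | None = None  # None -> skimage percentile defaults
    canny_high: float | None = None
    min_component: int = 20
    bridge_px: int = 3


@dataclass(frozen=True)
class RhtConfig:
    """Randomized-Hough detector parameters.

    ``min_pair_distance=None`` resolves to 5% of the point-cloud bounding-box
    diagonal; ``0`` disables the constraint (plain RHT sampling).
    """

    n_samples: int = 2000
    min_pair_distance: float | None = None
    n_bins: int = 256
    vote_threshold: int = 15
    inlier_tol_px: float = 2.0
    min_inlier_fraction: float = 0.5  # circle-stage acceptance
    max_attempt_factor: int = 20
    seed: int = 0
    edge: EdgeConfig = field(default_factory=EdgeConfig)


@dataclass(frozen=True)
class DetectionResult:
    """Outcome of the cascaded eye detector with stage provenance."""

    ellipse: Ellipse | None
    stage: str | None  # "circle" | "ellipse" | None
    circle_attempted: bool = False
    ellipse_attempted: bool = False


def preprocess_frame(frame: np.ndarray, config: EdgeConfig | None = None) -> np.ndarray:
    """Edge-pixel coordinates ``(x, y)`` of a frame after detection + denoising."""
    config = config or EdgeConfig()
    img = np.asarray(frame)
    if img.size == 0:
        raise ValueError("empty image")
    if img.ndim == 3:
        gray = img[..., :3].astype(float) @ np.array([0.299, 0.587, 0.114])
        if img.dtype == np.uint8:
            gray /= 255.0
    else:
        gray = img.astype(float)
        if img.dtype == np.uint8:
            gray /= 255.0

    levels = np.unique(img.reshape(-1, img.shape[-1]) if img.ndim == 3 else img)
    if img.ndim == 2 and len(levels) <= 2 and (gray > gray.min()).mean() < 0.2:
        edges = gray > gray.min() if len(levels) == 2 else np.zeros_like(gray, bool)
    else:
        edges = skfeature.canny(
            gray,
            sigma=config.canny_sigma,
            low_threshold=config.canny_low,
            high_threshold=config.canny_high,
        )

    if config.min_component > 1 and edges.any():
        dilated = ndimage.binary_dilation(edges, iterations=config.bridge_px)
        labels, n = ndimage.label(dilated)
        if n:
            sizes = ndimage.sum_labels(edges, labels, index=np.arange(1, n + 1))
            keep = np.zeros(n + 1, dtype=bool)
            keep[1:] = sizes >= config.min_component
            edges = edges & keep[labels]

    ys, xs = np.nonzero(edges)
    return np.stack([xs, ys], axis=1).astype(int)


def _pairwise_ok(groups: np.ndarray, min_dist: float) -> np.ndarray:
    """Mask of groups whose points are pairwise >= min_dist apart."""
    diff = groups[:, :, None, :] - groups[:, None, :, :]
    d2 = (diff**2).sum(axis=-1)
    k = groups.shape[1]
    iu = np.triu_indices(k, 1)
    return (d2[:, iu[0], iu[1]] >= min_dist**2).all(axis=1)


def sample_groups(
    points: np.ndarray,
    k: int,
    n_groups: int,
    min_pair_distance: float,
    rng: np.random.Generator,
    max_attempt_factor: int = 20,
) -> np.ndarray:
    """Up to ``n_groups`` index groups of ``k`` distinct points satisfying the
    pairwise distance constraint.  Rejection sampling in vectorized batches;
    gives up (returning what it has) after ``max_attempt_factor * n_groups``
    candidate draws."""
    pts = np.asarray(points, dtype=float)
    n = pts.shape[0]
    if k > n:
        raise ValueError(f"cannot sample {k} points from {n}")
    accepted: list[np.ndarray] = []
    total = 0
    budget = max_attempt_factor * n_groups
    while total < n_groups and budget > 0:
        # fixed batch size keeps the accepted-group sequence a prefix across
        # different n_groups budgets with the same rng seed
        batch = min(512, budget)
        budget -= batch
        # per-row distinct indices via argpartition of random keys
        keys = rng.random((batch, n))
        idx = np.argpartition(keys, k - 1, axis=1)[:, :k]
        if min_pair_distance > 0:
            ok = _pairwise_ok(pts[idx], min_pair_distance)
            idx = idx[ok]
        if idx.size:
            take = idx[: n_groups - total]
            accepted.append(take)
            total += take.shape[0]
    if not accepted:
        return np.empty((0, k), dtype=int)
    return np.concatenate(accepted, axis=0)


def sample_group(
    points: np.ndarray,
    k: int,
    min_pair_distance: float,
    rng: np.random.Generator,
    max_attempts: int = 100,
) -> np.ndarray | None:
    """One admissible group of ``k`` points, or ``None`` after bounded rejection."""
    pts = np.asarray(points, dtype=float)
    idx = sample_groups(pts, k, 1, min_pair_distance, rng, max_attempt_factor=max_attempts)
    if idx.shape[0] == 0:
        return None
    return pts[idx[0]]


def _resolve_min_dist(points: np.ndarray, config: RhtConfig) -> float:
    if config.min_pair_distance is not None:
        return config.min_pair_distance
    span = points.max(axis=0) - points.min(axis=0)
    return 0.05 * float(np.hypot(span[0], span[1]))


def _accumulate_1d(votes: np.ndarray, n_bins: int) -> tuple[int, float]:
    """Peak count and peak-bin center of a 1-D accumulator.

    The bin range is the 0.5-99.5 percentile band of the votes (a single wild
    conic would otherwise stretch min/max-based bins arbitrarily wide).
    """
    lo, hi = np.percentile(votes, [0.5, 99.5])
    if hi <= lo:
        lo, hi = lo - 0.5, hi + 0.5
    counts, edges = np.histogram(votes, bins=n_bins, range=(lo, hi))
    peak = int(np.argmax(counts))
    # parameter estimate: median of the votes in the peak bin and its two
    # neighbours (the raw bin center is quantized to the bin width, which can
    # be coarse when noise votes stretch the accumulator range)
    sel = votes[(votes >= edges[max(peak - 1, 0)]) & (votes <= edges[min(peak + 2, n_bins)])]
    center = float(np.median(sel)) if sel.size else 0.5 * (edges[peak] + edges[peak + 1])
    return int(counts[peak]), float(center)


def detect_ellipse_rht(points: np.ndarray, config: RhtConfig) -> Ellipse | None:
    """Ellipse detection: 5-point groups voted into five 1-D accumulators."""
    pts = np.asarray(points, dtype=float)
    if pts.shape[0] < 5:
        raise ValueError(f"need at least 5 points, got {pts.shape[0]}")
    rng = np.random.default_rng(config.seed)
    min_dist = _resolve_min_dist(pts, config)
    idx = sample_groups(
        pts, 5, config.n_samples, min_dist, rng, config.max_attempt_factor
    )
    if idx.shape[0] == 0:
        return None
    params, valid = fit_conics_batch(pts[idx])
    # vote only parameter vectors that satisfy the ellipse discriminant
    is_ellipse = valid & (params[:, 0] ** 2 - params[:, 1] < 0)
    votes = params[is_ellipse]
    if votes.shape[0] == 0:
        return None

    centers = np.empty(5)
    for d in range(5):
        count, center = _accumulate_1d(votes[:, d], config.n_bins)
        if count < config.vote_threshold:
            return None
        centers[d] = center

    conic = ConicParams(*centers)
    try:
        hypothesis = conic.to_ellipse()
    except ValueError:
        return None
    return _refine_ellipse(hypothesis, pts, config) or hypothesis


def _refine_ellipse(hypothesis: Ellipse, pts: np.ndarray, config: RhtConfig) -> Ellipse | None:
    """Two rounds of inlier selection + least-squares conic refit."""
    current = hypothesis
    for _ in range(2):
        dist = current.approx_distance(pts)
        inliers = pts[dist <= config.inlier_tol_px]
        if inliers.shape[0] < 5:
            return None
        conic = fit_conic_lstsq(inliers)
        if conic is None or not conic.is_ellipse():
            return None
        try:
            current = conic.to_ellipse()
        except ValueError:
            return None
    return current


def detect_circle_rht(points: np.ndarray, config: RhtConfig) -> Circle | None:
    """Circle detection: 3-point groups voted into (cx, cy, r) accumulators.

    Fails (returns ``None``) when any accumulator peak is below
    ``vote_threshold`` or when fewer than ``min_inlier_fraction`` of the edge
    points lie within ``inlier_tol_px`` of the winning circle — the latter is
    what rejects elliptical iris contours and defers them to the ellipse stage.
    """
    pts = np.asarray(points, dtype=float)
    if pts.shape[0] < 3:
        raise ValueError(f"need at least 3 points, got {pts.shape[0]}")
    rng = np.random.default_rng(config.seed)
    min_dist = _resolve_min_dist(pts, config)
    idx = sample_groups(
        pts, 3, config.n_samples, min_dist, rng, config.max_attempt_factor
    )
    if idx.shape[0] == 0:
        return None
    params, valid = fit_circles_batch(pts[idx])
    votes = params[valid]
    if votes.shape[0] == 0:
        return None

    centers = np.empty(3)
    for d in range(3):
        count, center = _accumulate_1d(votes[:, d], config.n_bins)
        if count < config.vote_threshold:
            return None
        centers[d] = center
    if centers[2] <= 0:
        return None
    circle = Circle(centers[0], centers[1], centers[2])

    for _ in range(2):
        dist = np.abs(np.hypot(pts[:, 0] - circle.cx, pts[:, 1] - circle.cy) - circle.r)
        inliers = pts[dist <= config.inlier_tol_px]
        if inliers.shape[0] / pts.shape[0] < config.min_inlier_fraction:
            return None
        refined = fit_circle_lstsq(inliers)
        if refined is None:
            return None
        circle = refined
    return circle


def detect_eye(frame: np.ndarray, config: RhtConfig | None = None) -> DetectionResult:
    """Cascaded eye localization: edges -> circle RHT -> (on failure) ellipse RHT."""
    config = config or RhtConfig()
    points = preprocess_frame(frame, config.edge)
    if points.shape[0] < 5:
        return DetectionResult(None, None)
    circle = detect_circle_rht(points, config)
    if circle is not None:
        return DetectionResult(circle.to_ellipse(), "circle", circle_attempted=True)
    ellipse = detect_ellipse_rht(points, config)
    if ellipse is not None:
        return DetectionResult(ellipse, "ellipse", True, True)
    return DetectionResult(None, None, True, True)


def detection_correct(
    detected: Ellipse,
    iris_gt: Ellipse,
    limbus_gt: Ellipse,
    n_boundary: int = 360,
    tol: float = 0.02,
) -> bool:
    """Band criterion for a correct detection: the detected ellipse encircles
    the iris and is itself encircled by the limbus (checked on a dense
    boundary sampling).

    ``tol`` is a containment slack in normalized-radius units (default 0.02,
    about one pixel at iris scale) absorbing the pixel quantization of edge
    contours; pass 0 for a strict geometric check.
    """
    if n_boundary < 360:
        n_boundary = 360
    iris_pts = iris_gt.boundary_points(n_boundary)
    det_pts = detected.boundary_points(n_boundary)
    return bool(
        detected.contains(iris_pts, tol=tol).all()
        and limbus_gt.contains(det_pts, tol=tol).all()
    )
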