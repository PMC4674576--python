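"""Cataract hardness grading from the tissue in front of the probe tip.

The tissue patch ahead of the probe tip is normalized to 32x32 and encoded as
a color feature vector

    f(I) = (r_1, g_1, b_1, ..., r_n, g_n, b_n,
            rbar_1, gbar_1, bbar_1, ..., rbar_m, gbar_m, bbar_m)

with ``n = 1024`` raw pixel colors in row-major order followed by the
``m = 64`` mean colors of an 8x8 grid of 4x4-pixel cells (also row-major),
giving a constant dimension of ``3 (n + m) = 3264`` with channels scaled to
``[0, 1]``.  The cell means duplicate information already present in the raw
pixels but make the vector robust to pixel-level noise; a means-only mode is
available for compactness.

Classification is a two-stage cascade of RBF-kernel SVMs: stage 1 identifies
whether the tissue is normal (label 0) — in which case stage 2 is *never*
invoked, the contract that protects normal tissue — and stage 2 assigns the
Emery-Little hardness grade 1-5 by one-vs-one voting.  A 5-nearest-neighbour
classifier over the same features serves as the conventional baseline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from skimage.transform import resize
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.svm import SVC

from .geometry import BoundingBox, Ellipse

__all__ = [
    "TissuePatch",
    "GradingConfig",
    "GradingCascade",
    "extract_tissue_roi",
    "extract_features",
    "train_cascade",
    "grade",
    "knn_baseline",
]

PATCH_SIZE = 32
GRID_CELLS = 8  # per axis
N_CLASSES = 6


@dataclass(frozen=True)
class TissuePatch:
    """RGB tissue patch normalized to 32x32, with its source location."""

    pixels: np.ndarray  # (32, 32, 3) uint8
    frame_index: int = -1
    source_roi: BoundingBox | None = None

    def __post_init__(self):
        p = np.asarray(self.pixels)
        if p.shape != (PATCH_SIZE, PATCH_SIZE, 3):
            raise ValueError(f"patch must be {PATCH_SIZE}x{PATCH_SIZE}x3, got {p.shape}")


def extract_tissue_roi(
    frame: np.ndarray,
    probe_box: BoundingBox,
    eye: Ellipse,
    roi_size: int = 32,
    frame_index: int = -1,
) -> TissuePatch:
    """Square ROI just beyond the probe tip, toward the eye center.

    The tip is the midpoint of the probe-box edge nearest the eye center; the
    ROI is centered half a side beyond the tip along the tip-to-eye-center
    direction, so the sampled tissue is the material the probe is about to
    emulsify.  When the geometry degenerates (eye center inside the probe
    box) the ROI is placed above the box (toward -y).
    """
    h, w = frame.shape[:2]
    ecx, ecy = eye.center
    edges = {
        "top": (probe_box.cx, probe_box.y),
        "bottom": (probe_box.cx, probe_box.y2),
        "left": (probe_box.x, probe_box.cy),
        "right": (probe_box.x2, probe_box.cy),
    }
    order = ["top", "bottom", "left", "right"]  # deterministic tie-break
    dists = {k: math.hypot(ecx - v[0], ecy - v[1]) for k, v in edges.items()}
    best = min(order, key=lambda k: (round(dists[k], 9), order.index(k)))
    tip = edges[best]

    degenerate = (
        probe_box.x <= ecx <= probe_box.x2 and probe_box.y <= ecy <= probe_box.y2
    ) or math.hypot(ecx - tip[0], ecy - tip[1]) < 1e-9
    if degenerate:
        tip = edges["top"]
        ux, uy = 0.0, -1.0
    else:
        dx, dy = ecx - tip[0], ecy - tip[1]
        norm = math.hypot(dx, dy)
        ux, uy = dx / norm, dy / norm

    cx = tip[0] + ux * roi_size / 2.0
    cy = tip[1] + uy * roi_size / 2.0
    x0 = int(round(cx - roi_size / 2.0))
    y0 = int(round(cy - roi_size / 2.0))
    x0c, y0c = max(x0, 0), max(y0, 0)
    x1c, y1c = min(x0 + roi_size, w), min(y0 + roi_size, h)
    if x1c - x0c < 4 or y1c - y0c < 4:
        raise ValueError("tissue ROI falls outside the frame")
    if not eye.contains(np.array([[cx, cy]]), tol=0.05)[0]:
        raise ValueError("tissue ROI center lies outside the eye")

    crop = np.asarray(frame)[y0c:y1c, x0c:x1c, :3]
    patch = resize(
        crop.astype(float), (PATCH_SIZE, PATCH_SIZE, 3), order=1,
        mode="edge", anti_aliasing=False, preserve_range=True,
    )
    roi = BoundingBox(float(x0c), float(y0c), float(x1c - x0c), float(y1c - y0c))
    return TissuePatch(np.clip(np.rint(patch), 0, 255).astype(np.uint8), frame_index, roi)


def extract_features(patch: TissuePatch | np.ndarray, means_only: bool = False) -> np.ndarray:
    """Color feature vector of a normalized patch (values in [0, 1])."""
    pixels = patch.pixels if isinstance(patch, TissuePatch) else np.asarray(patch)
    if pixels.shape != (PATCH_SIZE, PATCH_SIZE, 3):
        raise ValueError(f"expected {PATCH_SIZE}x{PATCH_SIZE}x3 patch, got {pixels.shape}")
    img = pixels.astype(float) / 255.0
    cell = PATCH_SIZE // GRID_CELLS
    cell_means = img.reshape(GRID_CELLS, cell, GRID_CELLS, cell, 3).mean(axis=(1, 3))
    if means_only:
        return cell_means.reshape(-1)
    return np.concatenate([img.reshape(-1), cell_means.reshape(-1)])


@dataclass(frozen=True)
class GradingConfig:
    """Training configuration for the cascade.

    The hyperparameter grid is logarithmic in C and the RBF width gamma;
    the search runs on a stratified subsample of at most ``cv_subsample``
    patches (grid-search cost grows quadratically with the kernel matrix)
    and the selected parameters are refit on the full training set.
    """

    c_grid: tuple[float, ...] = (2.0**-2, 2.0**2, 2.0**6, 2.0**10)
    gamma_grid: tuple[float, ...] = (2.0**-10, 2.0**-6, 2.0**-2, 2.0**2)
    cv_folds: int = 5
    cv_subsample: int = 600
    means_only: bool = False
    seed: int = 0


class GradingCascade:
    """Two-stage grading: normal-vs-cataract, then hardness 1-5 (one-vs-one)."""

    def __init__(self, stage1: SVC, stage2: SVC, config: GradingConfig, cv_scores: dict):
        self.stage1 = stage1
        self.stage2 = stage2
        self.config = config
        self.cv_scores = cv_scores
        self.n_stage2_calls = 0

    def predict_features(self, features: np.ndarray) -> int:
        f = np.asarray(features)[None, :]
        if int(self.stage1.predict(f)[0]) == 0:
            return 0
        self.n_stage2_calls += 1
        return int(self.stage2.predict(f)[0])


def _grid_search(x, y, config: GradingConfig, rng) -> tuple[SVC, float]:
    if len(x) > config.cv_subsample:
        # stratified subsample for the hyperparameter search
        idx = []
        for cls in np.unique(y):
            members = np.nonzero(y == cls)[0]
            take = max(2, int(round(config.cv_subsample * members.size / len(y))))
            idx.append(rng.choice(members, size=min(take, members.size), replace=False))
        idx = np.concatenate(idx)
        xs, ys = x[idx], y[idx]
    else:
        xs, ys = x, y
    cv = StratifiedKFold(
        n_splits=config.cv_folds, shuffle=True, random_state=int(rng.integers(2**31))
    )
    search = GridSearchCV(
        SVC(kernel="rbf"),
        {"C": list(config.c_grid), "gamma": list(config.gamma_grid)},
        cv=cv,
        n_jobs=1,
    )
    search.fit(xs, ys)
    best = SVC(kernel="rbf", **search.best_params_)
    best.fit(x, y)
    return best, float(search.best_score_)


def train_cascade(
    patches: np.ndarray, labels: np.ndarray, config: GradingConfig | None = None
) -> GradingCascade:
    """Fit the cascade on labeled 32x32 patches (labels 0-5, all present)."""
    config = config or GradingConfig()
    labels = np.asarray(labels, dtype=int)
    present = set(np.unique(labels))
    missing = sorted(set(range(N_CLASSES)) - present)
    if missing:
        raise ValueError(f"training set is missing grade label(s) {missing}")
    feats = np.stack([extract_features(p, config.means_only) for p in patches])
    rng = np.random.default_rng(config.seed)

    y1 = (labels > 0).astype(int)
    stage1, score1 = _grid_search(feats, y1, config, rng)
    mask = labels > 0
    stage2, score2 = _grid_search(feats[mask], labels[mask], config, rng)
    return GradingCascade(
        stage1, stage2, config, {"stage1_cv": score1, "stage2_cv": score2}
    )


def grade(patch: TissuePatch | np.ndarray, cascade: GradingCascade) -> int:
    """Grade one patch; 0 short-circuits without consulting stage 2."""
    feats = extract_features(patch, cascade.config.means_only)
    return cascade.predict_features(feats)


def knn_baseline(
    train_features: np.ndarray,
    train_labels: np.ndarray,
    query_features: np.ndarray,
    k: int = 5,
) -> np.ndarray:
    """k-nearest-neighbour grading over feature vectors (Euclidean metric).

    Majority vote among the k nearest training samples; ties go to the tied
    label with the smallest mean neighbour distance.
    """
    x = np.asarray(train_features, dtype=float)
    y = np.asarray(train_labels, dtype=int)
    q = np.atleast_2d(np.asarray(query_features, dtype=float))
    if x.shape[0] == 0:
        raise ValueError("empty training set")
    if k > x.shape[0]:
        raise ValueError(f"k={k} exceeds training-set size {x.shape[0]}")
    # all pairwise distances in one BLAS call; exact enough for ranking
    x2 = (x * x).sum(axis=1)
    q2 = (q * q).sum(axis=1)
    d2 = np.maximum(q2[:, None] + x2[None, :] - 2.0 * (q @ x.T), 0.0)
    out = np.empty(q.shape[0], dtype=int)
    for i in range(q.shape[0]):
        d = np.sqrt(d2[i])
        nn = np.argpartition(d, k - 1)[:k]
        votes: dict[int, list[float]] = {}
        for j in nn:
            votes.setdefault(int(y[j]), []).append(float(d[j]))
        best = sorted(
            votes.items(), key=lambda kv: (-len(kv[1]), float(np.mean(kv[1])), kv[0])
        )[0][0]
        out[i] = best
    return out
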