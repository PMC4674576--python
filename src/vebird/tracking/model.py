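"""Object model for the nearest-neighbour stage and the variance filter."""

from __future__ import annotations

import math

import numpy as np
from scipy.ndimage import map_coordinates

from ..geometry import BoundingBox

__all__ = ["ObjectModel", "variance_filter", "nn_confirm", "extract_patch"]


def variance_filter(patch: np.ndarray, init_variance: float) -> bool:
    """Accept a patch unless its gray-value variance is smaller than half of
    the variance of the patch selected for tracking."""
    if init_variance < 0:
        raise ValueError("init_variance must be non-negative")
    return float(np.var(patch)) >= 0.5 * init_variance


def extract_patch(gray: np.ndarray, box: BoundingBox, size: int = 15) -> np.ndarray:
    """Resample a box of a gray frame to ``size x size``, zero-mean."""
    fx = (np.arange(size) + 0.5) / size
    xs = box.x + fx * box.w - 0.5
    ys = box.y + fx * box.h - 0.5
    gx, gy = np.meshgrid(xs, ys, indexing="xy")
    vals = map_coordinates(
        gray.astype(np.float32), np.stack([gy.ravel(), gx.ravel()]), order=1, mode="nearest"
    ).reshape(size, size)
    return vals - vals.mean()


def _ncc01(a: np.ndarray, b: np.ndarray) -> float:
    """Normalized cross-correlation of zero-mean patches mapped to [0, 1]."""
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na < 1e-9 and nb < 1e-9:
        return 1.0
    if na < 1e-9 or nb < 1e-9:
        return 0.0
    return 0.5 * (float((a * b).sum() / (na * nb)) + 1.0)


class ObjectModel:
    """Positive/negative exemplar patches plus the initial-patch variance.

    Similarity of a query to a set is the maximum NCC (mapped to ``[0, 1]``)
    over the set's patches; the *relative* similarity is
    ``S+ / (S+ + S-)`` and the *conservative* similarity uses only the
    earliest half of the positive exemplars, so late (possibly drifted)
    additions cannot inflate the confidence that gates learning.
    """

    def __init__(self, init_variance: float, max_patches: int = 150):
        self.init_variance = float(init_variance)
        self.max_patches = max_patches
        self.positive: list[np.ndarray] = []
        self.negative: list[np.ndarray] = []

    def add_positive(self, patch: np.ndarray) -> None:
        if len(self.positive) < self.max_patches:
            self.positive.append(np.asarray(patch, dtype=np.float32))

    def add_negative(self, patch: np.ndarray) -> None:
        if len(self.negative) < self.max_patches:
            self.negative.append(np.asarray(patch, dtype=np.float32))

    def _max_sim(self, patch: np.ndarray, patches: list[np.ndarray]) -> float:
        if not patches:
            return 0.0
        stack = np.stack(patches).reshape(len(patches), -1)
        q = np.asarray(patch, dtype=np.float32).ravel()
        nq = np.linalg.norm(q)
        ns = np.linalg.norm(stack, axis=1)
        both_flat = (nq < 1e-9) & (ns < 1e-9)
        safe = np.where(ns < 1e-9, 1.0, ns) * (nq if nq >= 1e-9 else 1.0)
        corr = stack @ q / safe
        sims = 0.5 * (corr + 1.0)
        sims = np.where(both_flat, 1.0, np.where((ns < 1e-9) | (nq < 1e-9), 0.0, sims))
        return float(sims.max())

    def relative_similarity(self, patch: np.ndarray) -> float:
        sp = self._max_sim(patch, self.positive)
        sn = self._max_sim(patch, self.negative)
        if sp + sn <= 0:
            return 0.0
        return sp / (sp + sn)

    def conservative_similarity(self, patch: np.ndarray) -> float:
        half = self.positive[: max(1, math.ceil(len(self.positive) / 2))]
        sp = self._max_sim(patch, half)
        sn = self._max_sim(patch, self.negative)
        if sp + sn <= 0:
            return 0.0
        return sp / (sp + sn)


def nn_confirm(
    patch: np.ndarray, model: ObjectModel, threshold: float = 0.6
) -> tuple[float, float, bool]:
    """Nearest-neighbour reconfirmation.

    Returns ``(relative_similarity, conservative_similarity, label)`` with the
    label positive iff the relative similarity exceeds ``threshold``.
    """
    if not model.positive or not model.negative:
        raise ValueError("object model needs at least one positive and one negative patch")
    sr = model.relative_similarity(patch)
    sc = model.conservative_similarity(patch)
    return sr, sc, sr > threshold
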