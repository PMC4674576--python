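"""Tracking evaluation: overlap rate (OR) and precision.

The overlap rate between a tracked region and the ground truth is

    OR = area(ROI_T ∩ ROI_G) / min(area(ROI_T), area(ROI_G)),

a deliberately lenient variant of the usual intersection-over-union (the
probe's true spatial extent is ill-defined, so a tracked box contained in the
annotation — or containing it — scores 1).  A frame is correct when OR is
strictly larger than 0.5, and precision is the exact ratio

    P = #correct / #frames.

When the tracker or the ground truth marks the probe absent, OR is undefined;
by default absent/absent counts correct and a present/absent mismatch counts
incorrect (configurable).
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

from .geometry import BoundingBox

__all__ = [
    "overlap_rate",
    "frame_correct",
    "precision",
    "TrackingEvaluation",
    "evaluate_tracking",
]

OR_THRESHOLD = 0.5


def overlap_rate(roi_t: BoundingBox, roi_g: BoundingBox) -> float:
    """Intersection area over the smaller box area; exact on integer boxes."""
    if roi_t.area <= 0 or roi_g.area <= 0:
        raise ValueError("boxes must have positive area")
    inter = roi_t.intersection_area(roi_g)
    # mathematically <= 1; clamp float round-off on non-integer boxes
    return min(inter / min(roi_t.area, roi_g.area), 1.0)


def frame_correct(or_value: float, threshold: float = OR_THRESHOLD) -> bool:
    """Strictly-greater comparison of the overlap rate with the threshold."""
    if not 0.0 <= or_value <= 1.0:
        raise ValueError(f"overlap rate must be in [0, 1], got {or_value}")
    return or_value > threshold


def precision(correctness) -> float:
    """Exact #correct / #frames of a boolean list."""
    flags = [bool(c) for c in correctness]
    if not flags:
        raise ValueError("empty correctness list")
    return float(Fraction(sum(flags), len(flags)))


@dataclass(frozen=True)
class TrackingEvaluation:
    or_values: list[float | None]  # None when either box is absent
    correct: list[bool]
    precision: float


def evaluate_tracking(
    trajectory,
    ground_truth,
    threshold: float = OR_THRESHOLD,
    absent_absent_correct: bool = True,
) -> TrackingEvaluation:
    """Per-frame OR/correctness and precision for a tracked trajectory.

    ``trajectory`` and ``ground_truth`` are equal-length sequences of
    ``BoundingBox`` or ``None`` (absent).
    """
    trajectory = list(trajectory)
    ground_truth = list(ground_truth)
    if len(trajectory) != len(ground_truth):
        raise ValueError(
            f"length mismatch: {len(trajectory)} predictions vs "
            f"{len(ground_truth)} ground-truth frames"
        )
    ors: list[float | None] = []
    correct: list[bool] = []
    for pred, gt in zip(trajectory, ground_truth):
        if pred is None or gt is None:
            ors.append(None)
            correct.append(pred is None and gt is None and absent_absent_correct)
        else:
            o = overlap_rate(pred, gt)
            ors.append(o)
            correct.append(frame_correct(o, threshold))
    return TrackingEvaluation(ors, correct, precision(correct))
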