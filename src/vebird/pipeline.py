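"""Per-frame composition of the three stages: detect -> track -> grade.

Each frame yields a :class:`FrameResult` with the eye ellipse, the probe box
and the grade, plus provenance flags (which detection stage fired, whether
the box came from the tracker or the detector, whether the grading cascade
reached stage 2).  Grading for frame t consumes only the detection and
tracking outputs of frame t — never future frames — and stage failures are
recorded in the result rather than aborting the run.

Eye detection is scheduled every ``eye_every`` frames and the last successful
detection is reused in between (the iris moves slowly relative to the probe);
set ``eye_every=1`` for per-frame detection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .eye_detection import RhtConfig, detect_eye
from .geometry import BoundingBox, Ellipse
from .grading import GradingCascade, extract_tissue_roi, grade
from .tracking import TldTracker, TrackerConfig

__all__ = ["PipelineConfig", "FrameResult", "run_pipeline"]


@dataclass(frozen=True)
class PipelineConfig:
    eye: RhtConfig = field(default_factory=RhtConfig)
    tracker: TrackerConfig = field(default_factory=TrackerConfig)
    eye_every: int = 10
    roi_size: int = 32


@dataclass(frozen=True)
class FrameResult:
    index: int
    eye: Ellipse | None
    probe: BoundingBox | None
    grade: int | None
    eye_stage: str | None = None  # "circle" | "ellipse" | None
    eye_fresh: bool = False  # detection ran on this frame (vs held)
    probe_source: str | None = None  # "tracker" | "detector" | None
    grade_stage2: bool | None = None  # cascade reached stage 2

    def __post_init__(self):
        if self.grade is not None and (self.eye is None or self.probe is None):
            raise ValueError("grade requires both eye and probe")


def run_pipeline(
    frames,
    init_box: BoundingBox,
    cascade: GradingCascade,
    config: PipelineConfig | None = None,
) -> list[FrameResult]:
    """Run the full stack over a frame sequence.

    ``init_box`` is the manual probe annotation of frame 1; ``cascade`` must
    be a fitted grading cascade.
    """
    config = config or PipelineConfig()
    frames = list(frames)
    if not frames:
        raise ValueError("no frames")

    results: list[FrameResult] = []
    tracker: TldTracker | None = None
    eye: Ellipse | None = None
    eye_stage: str | None = None
    for t, frame in enumerate(frames):
        fresh = t % config.eye_every == 0
        if fresh:
            det = detect_eye(np.asarray(frame), config.eye)
            if det.ellipse is not None:
                eye, eye_stage = det.ellipse, det.stage
            # on failure hold the previous detection (eye stays as-is)

        if tracker is None:
            tracker = TldTracker(frame, init_box, config.tracker)
            probe, source = init_box, "tracker"
        else:
            step = tracker.step(frame)
            probe, source = step.box, step.source

        grade_label = None
        stage2 = None
        if eye is not None and probe is not None:
            try:
                patch = extract_tissue_roi(
                    np.asarray(frame), probe, eye, config.roi_size, frame_index=t
                )
            except ValueError:
                patch = None
            if patch is not None:
                before = cascade.n_stage2_calls
                grade_label = grade(patch, cascade)
                stage2 = cascade.n_stage2_calls > before

        results.append(
            FrameResult(
                index=t,
                eye=eye,
                probe=probe,
                grade=grade_label,
                eye_stage=eye_stage,
                eye_fresh=fresh,
                probe_source=source,
                grade_stage2=stage2,
            )
        )
    return results
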