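"""File formats: numbered PNG frames, JSON ground-truth sidecars, JSON Lines
result streams, YAML configs and serialized grading models.

Conventions: boxes are ``[x, y, w, h]`` (0-based pixels, top-left origin);
ellipses are ``{"cx", "cy", "a", "b", "theta_rad"}``; absent values are JSON
``null``.
"""

from __future__ import annotations

import json
import re
from pathlib import Path

import imageio.v3 as iio
import joblib
import numpy as np
import yaml

from .eye_detection import EdgeConfig, RhtConfig
from .geometry import BoundingBox, Ellipse
from .grading import GradingCascade
from .pipeline import FrameResult, PipelineConfig
from .tracking import TrackerConfig

MODEL_FORMAT_VERSION = 1

__all__ = [
    "write_frames",
    "read_frames",
    "box_to_json",
    "box_from_json",
    "ellipse_to_json",
    "ellipse_from_json",
    "write_ground_truth",
    "read_ground_truth",
    "write_results_jsonl",
    "save_cascade",
    "load_cascade",
    "load_config",
    "load_synth_spec",
]


def write_frames(frames, directory: str | Path, prefix: str = "frame") -> list[Path]:
    """Write frames as numbered PNGs (``frame_000000.png``, ...)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, frame in enumerate(frames):
        p = directory / f"{prefix}_{i:06d}.png"
        iio.imwrite(p, np.asarray(frame))
        paths.append(p)
    return paths


def read_frames(path: str | Path) -> list[np.ndarray]:
    """Read a directory of numbered PNGs (sorted numerically) or a video file."""
    path = Path(path)
    if path.is_dir():
        files = sorted(
            path.glob("*.png"),
            key=lambda p: [int(s) if s.isdigit() else s for s in re.split(r"(\d+)", p.name)],
        )
        if not files:
            raise FileNotFoundError(f"no PNG frames under {path}")
        return [iio.imread(f) for f in files]
    return [np.asarray(f) for f in iio.imiter(path)]


def box_to_json(box: BoundingBox | None):
    return None if box is None else [box.x, box.y, box.w, box.h]


def box_from_json(data) -> BoundingBox | None:
    return None if data is None else BoundingBox(*map(float, data))


def ellipse_to_json(e: Ellipse | None):
    if e is None:
        return None
    return {"cx": e.cx, "cy": e.cy, "a": e.a, "b": e.b, "theta_rad": e.theta}


def ellipse_from_json(data) -> Ellipse | None:
    if data is None:
        return None
    return Ellipse(data["cx"], data["cy"], data["a"], data["b"], data["theta_rad"])


def write_ground_truth(path: str | Path, boxes=None, iris=None, limbus=None, grade=None) -> None:
    doc = {}
    if boxes is not None:
        doc["boxes"] = [box_to_json(b) for b in boxes]
    if iris is not None:
        doc["iris"] = ellipse_to_json(iris)
    if limbus is not None:
        doc["limbus"] = ellipse_to_json(limbus)
    if grade is not None:
        doc["grade"] = int(grade)
    Path(path).write_text(json.dumps(doc, indent=1))


def read_ground_truth(path: str | Path) -> dict:
    doc = json.loads(Path(path).read_text())
    out = dict(doc)
    if "boxes" in doc:
        out["boxes"] = [box_from_json(b) for b in doc["boxes"]]
    if "iris" in doc:
        out["iris"] = ellipse_from_json(doc["iris"])
    if "limbus" in doc:
        out["limbus"] = ellipse_from_json(doc["limbus"])
    return out


def write_results_jsonl(path: str | Path, results: list[FrameResult]) -> None:
    """One FrameResult per line (streaming-friendly)."""
    with open(path, "w") as fh:
        for r in results:
            fh.write(
                json.dumps(
                    {
                        "index": r.index,
                        "eye": ellipse_to_json(r.eye),
                        "probe": box_to_json(r.probe),
                        "grade": r.grade,
                        "eye_stage": r.eye_stage,
                        "eye_fresh": r.eye_fresh,
                        "probe_source": r.probe_source,
                        "grade_stage2": r.grade_stage2,
                    }
                )
                + "\n"
            )


def save_cascade(path: str | Path, cascade: GradingCascade) -> None:
    joblib.dump(
        {
            "format": "vebird-grading-cascade",
            "format_version": MODEL_FORMAT_VERSION,
            "cascade": cascade,
        },
        path,
    )


def load_cascade(path: str | Path) -> GradingCascade:
    doc = joblib.load(path)
    if not isinstance(doc, dict) or doc.get("format") != "vebird-grading-cascade":
        raise ValueError(f"{path} is not a grading-cascade model file")
    if doc.get("format_version") != MODEL_FORMAT_VERSION:
        raise ValueError(f"unsupported model format version {doc.get('format_version')}")
    return doc["cascade"]


def load_synth_spec(path: str | Path):
    """Load a synthetic-fixture spec from YAML or JSON.

    The document needs a ``kind`` key (``eye_image`` / ``probe_video`` /
    ``tissue_color`` / ``surgery_video``); ellipse-valued fields are given as
    ``{cx, cy, a, b, theta_rad}`` objects and sequence fields as lists.
    """
    from . import synthetic

    doc = yaml.safe_load(Path(path).read_text())
    kinds = {
        "eye_image": synthetic.EyeImageSpec,
        "probe_video": synthetic.ProbeVideoSpec,
        "tissue_color": synthetic.TissueColorModel,
        "surgery_video": synthetic.SurgeryVideoSpec,
    }
    kind = doc.pop("kind", None)
    if kind not in kinds:
        raise ValueError(f"spec 'kind' must be one of {sorted(kinds)}, got {kind!r}")
    for key, value in list(doc.items()):
        if isinstance(value, dict) and {"cx", "cy", "a", "b"} <= set(value):
            doc[key] = ellipse_from_json(value)
        elif key in ("image_size", "frame_size", "probe_size") and value is not None:
            doc[key] = tuple(value)
        elif key == "trajectory" and value is not None:
            doc[key] = np.asarray(value, dtype=float)
        elif key == "occlusion_frames" and value is not None:
            doc[key] = frozenset(int(v) for v in value)
        elif key == "grade_means" and value is not None:
            doc[key] = np.asarray(value, dtype=np.uint8)
    return kinds[kind](**doc)


def _build(cls, data: dict):
    return cls(**data) if data else cls()


def load_config(path: str | Path | None) -> PipelineConfig:
    """Pipeline config from a YAML file with sections
    ``eye_detection`` / ``tracking`` / ``pipeline`` (all optional)."""
    if path is None:
        return PipelineConfig()
    doc = yaml.safe_load(Path(path).read_text()) or {}
    eye_doc = dict(doc.get("eye_detection", {}))
    edge = _build(EdgeConfig, eye_doc.pop("edge", {}))
    eye = RhtConfig(edge=edge, **eye_doc)
    tracker = _build(TrackerConfig, doc.get("tracking", {}))
    pipe = doc.get("pipeline", {})
    return PipelineConfig(
        eye=eye,
        tracker=tracker,
        eye_every=int(pipe.get("eye_every", 10)),
        roi_size=int(pipe.get("roi_size", 32)),
    )
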