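"""Seeded synthetic fixtures for the detection / tracking / grading stages.

Real phacoemulsification microscope footage is not redistributable, so every
algorithm in this package is exercised on synthetic data carrying the
statistical structure the algorithm assumes:

* noisy edge images containing one iris-like ellipse (for the randomized
  Hough transform detector),
* videos of a rigid textured probe moving over a background whose appearance
  drifts slowly from frame to frame (the regime in which a tracking-by-
  detection ensemble starts mislabelling the probe as background),
* 32x32 tissue patches whose dominant color follows the Emery-Little nuclear
  hardness scale (normal tissue plus grades I-V),
* a composed "surgery" video (iris disc + moving probe + graded tissue color)
  for end-to-end pipeline runs.

All generators are pure functions of their spec, seed included: the same spec
produces bit-identical output, and ground truth always accompanies the data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from .geometry import BoundingBox, Ellipse

__all__ = [
    "EyeImageSpec",
    "EyeImageSample",
    "generate_eye_image",
    "ProbeVideoSpec",
    "ProbeVideoSample",
    "generate_probe_video",
    "bouncing_trajectory",
    "orbit_trajectory",
    "TissueColorModel",
    "TissuePatchSet",
    "generate_tissue_patches",
    "SurgeryVideoSpec",
    "SurgeryVideoSample",
    "generate_surgery_video",
    "DEFAULT_GRADE_COLORS",
]

# Default per-grade mean colors (RGB, 0-255) verbalizing the Emery-Little
# color descriptions: 0 normal tissue (pinkish), 1 transparent/non-nuclear,
# 2 yellow or yellow-white, 3 dark yellow, 4 brown or amber, 5 dark brown or
# black.  Configurable through TissueColorModel.
DEFAULT_GRADE_COLORS = np.array(
    [
        (200, 160, 160),
        (235, 235, 235),
        (230, 220, 140),
        (190, 150, 40),
        (150, 100, 40),
        (70, 50, 30),
    ],
    dtype=np.uint8,
)


def _check_ellipse_inside_image(e: Ellipse, size: tuple[int, int], name: str) -> None:
    w, h = size
    pts = e.boundary_points(360)
    if pts[:, 0].min() <= 0 or pts[:, 0].max() >= w - 1:
        raise ValueError(f"{name} exceeds image bounds horizontally")
    if pts[:, 1].min() <= 0 or pts[:, 1].max() >= h - 1:
        raise ValueError(f"{name} exceeds image bounds vertically")


@dataclass(frozen=True)
class EyeImageSpec:
    """Spec for a noisy edge image containing one iris contour.

    ``limbus_ellipse`` is ground truth only (the outer boundary used by the
    detection-correctness band); its points are not drawn.
    """

    image_size: tuple[int, int] = (256, 256)  # (width, height)
    iris_ellipse: Ellipse = field(
        default_factory=lambda: Ellipse(128.0, 128.0, 60.0, 60.0, 0.0)
    )
    limbus_ellipse: Ellipse | None = None  # default: iris scaled 1.3x
    n_contour_points: int = 200
    noise_fraction: float = 0.3
    seed: int = 0

    def resolved_limbus(self) -> Ellipse:
        return self.limbus_ellipse if self.limbus_ellipse is not None else self.iris_ellipse.scaled(1.3)

    def validate(self) -> None:
        if not 0.0 <= self.noise_fraction < 1.0:
            raise ValueError(f"noise_fraction must be in [0, 1), got {self.noise_fraction}")
        if self.n_contour_points < 5:
            raise ValueError("n_contour_points must be at least 5")
        limbus = self.resolved_limbus()
        _check_ellipse_inside_image(self.iris_ellipse, self.image_size, "iris_ellipse")
        _check_ellipse_inside_image(limbus, self.image_size, "limbus_ellipse")
        rad = limbus.normalized_radius(self.iris_ellipse.boundary_points(360))
        if rad.max() >= 1.0:
            raise ValueError("iris_ellipse must lie strictly inside limbus_ellipse")


@dataclass(frozen=True)
class EyeImageSample:
    edge_image: np.ndarray  # (H, W) uint8 in {0, 1}
    points: np.ndarray  # (n, 2) int (x, y); contour points first
    n_contour: int
    iris: Ellipse
    limbus: Ellipse

    @property
    def contour_points(self) -> np.ndarray:
        return self.points[: self.n_contour]

    @property
    def noise_points(self) -> np.ndarray:
        return self.points[self.n_contour:]


def generate_eye_image(spec: EyeImageSpec) -> EyeImageSample:
    """Render the iris contour as quantized edge points plus uniform noise.

    Exactly ``n_contour_points`` distinct pixels are sampled on the iris
    ellipse, followed by ``ceil(f / (1 - f) * n)`` uniformly scattered noise
    points so that the true-point fraction of the output is ``1 - f``.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    w, h = spec.image_size
    n = spec.n_contour_points

    chosen: list[tuple[int, int]] = []
    seen: set[tuple[int, int]] = set()
    guard = 0
    while len(chosen) < n:
        guard += 1
        if guard > 100:
            raise ValueError(
                "could not place the requested number of distinct contour pixels; "
                "the ellipse is too small for n_contour_points"
            )
        t = rng.uniform(0.0, 2 * math.pi, size=2 * n)
        ct, st = math.cos(spec.iris_ellipse.theta), math.sin(spec.iris_ellipse.theta)
        ex = spec.iris_ellipse.a * np.cos(t)
        ey = spec.iris_ellipse.b * np.sin(t)
        xs = np.rint(spec.iris_ellipse.cx + ex * ct - ey * st).astype(int)
        ys = np.rint(spec.iris_ellipse.cy + ex * st + ey * ct).astype(int)
        for x, y in zip(xs, ys):
            key = (int(x), int(y))
            if key not in seen:
                seen.add(key)
                chosen.append(key)
                if len(chosen) == n:
                    break
    contour = np.array(chosen, dtype=int)

    if spec.noise_fraction > 0:
        m = math.ceil(spec.noise_fraction / (1.0 - spec.noise_fraction) * n)
        noise = np.stack(
            [rng.integers(0, w, size=m), rng.integers(0, h, size=m)], axis=1
        )
    else:
        noise = np.empty((0, 2), dtype=int)

    points = np.concatenate([contour, noise], axis=0)
    image = np.zeros((h, w), dtype=np.uint8)
    image[points[:, 1], points[:, 0]] = 1
    return EyeImageSample(image, points, n, spec.iris_ellipse, spec.resolved_limbus())


def _texture_fields(rng, shape, smoothness):
    f1 = gaussian_filter(rng.standard_normal(shape), smoothness)
    f2 = gaussian_filter(rng.standard_normal(shape), smoothness)
    f1 /= max(f1.std(), 1e-9)
    f2 /= max(f2.std(), 1e-9)
    return f1, f2


def bouncing_trajectory(
    n_frames: int,
    frame_size: tuple[int, int],
    probe_size: tuple[int, int],
    start: tuple[float, float] = (10.0, 10.0),
    velocity: tuple[float, float] = (1.5, 0.8),
    margin: int = 2,
) -> np.ndarray:
    """Top-left positions of a box reflecting off the frame borders."""
    w, h = frame_size
    pw, ph = probe_size
    x, y = float(start[0]), float(start[1])
    vx, vy = float(velocity[0]), float(velocity[1])
    out = np.empty((n_frames, 2))
    for t in range(n_frames):
        out[t] = (x, y)
        x += vx
        y += vy
        if x < margin or x > w - pw - margin:
            vx = -vx
            x = min(max(x, margin), w - pw - margin)
        if y < margin or y > h - ph - margin:
            vy = -vy
            y = min(max(y, margin), h - ph - margin)
    return out


def orbit_trajectory(
    n_frames: int,
    center: tuple[float, float],
    radius: float,
    probe_size: tuple[int, int],
    omega: float = 0.05,
    phase: float = 0.0,
) -> np.ndarray:
    """Top-left positions of a box whose center orbits ``center``."""
    t = np.arange(n_frames)
    cx = center[0] + radius * np.cos(phase + omega * t)
    cy = center[1] + radius * np.sin(phase + omega * t)
    return np.stack([cx - probe_size[0] / 2.0, cy - probe_size[1] / 2.0], axis=1)


@dataclass(frozen=True)
class ProbeVideoSpec:
    """Spec for a rigid textured probe moving over a drifting background.

    The background does not translate: its appearance rotates through a
    two-field phase blend (``cos(phi) F1 + sin(phi) F2`` with ``phi`` advancing
    by ``background_drift_rate`` radians per frame), i.e. a smooth everywhere-
    small appearance change with no coherent motion, emulating the surgical
    background whose look changes while the probe stays in its box.

    The drawn probe is a textured bar occupying the central
    ``bar_height_frac`` of the annotated box, so the annotation rectangle
    contains background above and below the instrument (as a rectangle
    annotation of a slender probe does).
    """

    n_frames: int = 200
    frame_size: tuple[int, int] = (160, 120)  # (width, height)
    probe_size: tuple[int, int] = (40, 24)
    trajectory: np.ndarray | None = None  # (n_frames, 2) top-left; default bouncing
    background_drift_rate: float = 0.08  # radians of texture phase per frame
    background_contrast: float = 0.18
    background_smoothness: float = 5.0
    probe_contrast: float = 0.30
    bar_height_frac: float = 0.45
    occlusion_frames: frozenset[int] = frozenset()
    seed: int = 0

    def resolved_trajectory(self) -> np.ndarray:
        if self.trajectory is not None:
            traj = np.asarray(self.trajectory, dtype=float)
        else:
            traj = bouncing_trajectory(
                self.n_frames, self.frame_size, self.probe_size
            )
        if traj.shape != (self.n_frames, 2):
            raise ValueError(
                f"trajectory must have shape ({self.n_frames}, 2), got {traj.shape}"
            )
        return traj

    def validate(self) -> None:
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        traj = self.resolved_trajectory()
        if traj.shape[0] == 0:
            raise ValueError("empty trajectory")
        w, h = self.frame_size
        pw, ph = self.probe_size
        for t, (x, y) in enumerate(traj):
            if t in self.occlusion_frames:
                continue
            if x < 0 or y < 0 or x + pw > w or y + ph > h:
                raise ValueError(
                    f"trajectory leaves the frame at frame {t}: ({x:.1f}, {y:.1f})"
                )


@dataclass(frozen=True)
class ProbeVideoSample:
    frames: list[np.ndarray]  # (H, W, 3) uint8
    boxes: list[BoundingBox | None]  # ground truth; None on occlusion frames


def _gray_to_rgb8(gray: np.ndarray) -> np.ndarray:
    g8 = np.clip(gray * 255.0, 0, 255).astype(np.uint8)
    return np.stack([g8, g8, g8], axis=2)


def generate_probe_video(spec: ProbeVideoSpec) -> ProbeVideoSample:
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    w, h = spec.frame_size
    pw, ph = spec.probe_size
    traj = spec.resolved_trajectory()

    f1, f2 = _texture_fields(rng, (h, w), spec.background_smoothness)
    bar_h = max(2, int(round(ph * spec.bar_height_frac)))
    pad = (ph - bar_h) // 2
    # fixed probe texture: high-frequency pattern with a bright leading stripe
    tex = gaussian_filter(rng.standard_normal((bar_h, pw)), 1.0)
    tex /= max(tex.std(), 1e-9)
    probe_tex = np.clip(0.25 + spec.probe_contrast * tex, 0.0, 1.0)
    probe_tex[:, -3:] = 0.95  # bright tip stripe

    frames: list[np.ndarray] = []
    boxes: list[BoundingBox | None] = []
    for t in range(spec.n_frames):
        phi = spec.background_drift_rate * t
        bg = 0.55 + spec.background_contrast * (
            math.cos(phi) * f1 + math.sin(phi) * f2
        )
        frame = np.clip(bg, 0.0, 1.0)
        if t in spec.occlusion_frames:
            boxes.append(None)
        else:
            x0 = int(round(traj[t, 0]))
            y0 = int(round(traj[t, 1]))
            frame[y0 + pad : y0 + pad + bar_h, x0 : x0 + pw] = probe_tex
            boxes.append(BoundingBox(float(x0), float(y0), float(pw), float(ph)))
        frames.append(_gray_to_rgb8(frame))
    return ProbeVideoSample(frames, boxes)


@dataclass(frozen=True)
class TissueColorModel:
    """Per-grade mean colors and i.i.d. Gaussian per-channel noise."""

    grade_means: np.ndarray = field(default_factory=lambda: DEFAULT_GRADE_COLORS.copy())
    noise_scale: float = 10.0  # 8-bit units
    seed: int = 0

    def validate(self) -> None:
        means = np.asarray(self.grade_means)
        if means.shape != (6, 3):
            raise ValueError(f"grade_means must be (6, 3), got {means.shape}")
        if len(np.unique(means, axis=0)) != 6:
            raise ValueError("the six grade mean colors must be pairwise distinct")
        if self.noise_scale < 0:
            raise ValueError("noise_scale must be non-negative")


@dataclass(frozen=True)
class TissuePatchSet:
    patches: np.ndarray  # (N, 32, 32, 3) uint8
    labels: np.ndarray  # (N,) int in {0..5}


def generate_tissue_patches(model: TissueColorModel, n_per_grade: int) -> TissuePatchSet:
    """``n_per_grade`` 32x32 patches per grade: mean color + clipped Gaussian noise."""
    model.validate()
    if n_per_grade < 1:
        raise ValueError("n_per_grade must be >= 1")
    rng = np.random.default_rng(model.seed)
    means = np.asarray(model.grade_means, dtype=float)
    patches = []
    labels = []
    for grade in range(6):
        block = np.broadcast_to(
            means[grade], (n_per_grade, 32, 32, 3)
        ).astype(float)
        if model.noise_scale > 0:
            block = block + rng.normal(
                0.0, model.noise_scale, size=(n_per_grade, 32, 32, 3)
            )
        patches.append(np.clip(np.rint(block), 0, 255).astype(np.uint8))
        labels.append(np.full(n_per_grade, grade, dtype=int))
    return TissuePatchSet(np.concatenate(patches), np.concatenate(labels))


@dataclass(frozen=True)
class SurgeryVideoSpec:
    """Composed end-to-end fixture: iris disc, moving probe, graded tissue color."""

    n_frames: int = 100
    frame_size: tuple[int, int] = (240, 180)
    iris: Ellipse = field(default_factory=lambda: Ellipse(120.0, 90.0, 62.0, 62.0, 0.0))
    limbus: Ellipse | None = None  # default iris scaled 1.3x
    grade: int = 3
    probe_size: tuple[int, int] = (36, 20)
    orbit_radius: float = 24.0
    orbit_omega: float = 0.05
    color_model: TissueColorModel = field(default_factory=TissueColorModel)
    probe_contrast: float = 0.30
    seed: int = 0

    def resolved_limbus(self) -> Ellipse:
        return self.limbus if self.limbus is not None else self.iris.scaled(1.3)

    def validate(self) -> None:
        if not 0 <= self.grade <= 5:
            raise ValueError(f"grade must be in 0..5, got {self.grade}")
        self.color_model.validate()
        _check_ellipse_inside_image(self.iris, self.frame_size, "iris")
        _check_ellipse_inside_image(self.resolved_limbus(), self.frame_size, "limbus")


@dataclass(frozen=True)
class SurgeryVideoSample:
    frames: list[np.ndarray]  # (H, W, 3) uint8
    boxes: list[BoundingBox]  # probe ground truth
    iris: Ellipse
    limbus: Ellipse
    grade: int


def generate_surgery_video(spec: SurgeryVideoSpec) -> SurgeryVideoSample:
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    w, h = spec.frame_size
    pw, ph = spec.probe_size
    color = np.asarray(spec.color_model.grade_means, dtype=float)[spec.grade] / 255.0

    yy, xx = np.mgrid[0:h, 0:w]
    rad = spec.iris.normalized_radius(
        np.stack([xx.ravel(), yy.ravel()], axis=1)
    ).reshape(h, w)
    iris_mask = rad <= 1.0
    # dark limbal ring just outside the iris: its two edge contours (iris
    # boundary and ring outer edge) both lie inside the iris-limbus band, so
    # locking onto either is a correct detection
    rim_mask = (rad > 1.0) & (rad <= 1.04)

    sclera = 0.86 + gaussian_filter(rng.standard_normal((h, w)), 6.0) * 0.02
    base = np.empty((h, w, 3))
    base[...] = sclera[..., None]
    noise = rng.normal(0.0, spec.color_model.noise_scale / 255.0, size=(h, w, 3))
    base[iris_mask] = np.clip(color[None, :] + noise[iris_mask], 0.0, 1.0)
    base[rim_mask] = np.clip(color * 0.35, 0.0, 1.0)

    traj = orbit_trajectory(
        spec.n_frames,
        spec.iris.center,
        spec.orbit_radius,
        spec.probe_size,
        omega=spec.orbit_omega,
    )
    bar_h = max(2, int(round(ph * 0.45)))
    pad = (ph - bar_h) // 2
    tex = gaussian_filter(rng.standard_normal((bar_h, pw)), 1.0)
    tex /= max(tex.std(), 1e-9)
    probe_tex = np.clip(0.25 + spec.probe_contrast * tex, 0.0, 1.0)
    probe_tex[:, -3:] = 0.95

    frames: list[np.ndarray] = []
    boxes: list[BoundingBox] = []
    for t in range(spec.n_frames):
        frame = base.copy()
        x0 = int(round(traj[t, 0]))
        y0 = int(round(traj[t, 1]))
        frame[y0 + pad : y0 + pad + bar_h, x0 : x0 + pw] = probe_tex[..., None]
        frames.append(np.clip(frame * 255.0, 0, 255).astype(np.uint8))
        boxes.append(BoundingBox(float(x0), float(y0), float(pw), float(ph)))
    return SurgeryVideoSample(frames, boxes, spec.iris, spec.resolved_limbus(), spec.grade)
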