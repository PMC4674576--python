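"""Conic, ellipse, circle and bounding-box primitives.

The eye detector represents its hypotheses as conics in the reduced form

    x^2 + 2 b x y + c y^2 + 2 d x + 2 e y + f = 0

i.e. the general conic ``A x^2 + 2 B x y + C y^2 + 2 D x + 2 E y + F = 0``
normalized by ``A`` (valid for every ellipse, where ``A != 0``).  Under this
convention the ellipse condition ``B^2 - 4 A C < 0`` (with cross term ``2Bxy``,
so discriminant ``(2B)^2 - 4AC``) becomes ``b^2 - c < 0``.

Coordinates are 0-based pixels, x rightward, y downward, pixel centers at
integer coordinates.  Orientation angles are radians in ``[0, pi)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "ConicParams",
    "Ellipse",
    "Circle",
    "BoundingBox",
    "fit_conic_5pts",
    "fit_conics_batch",
    "fit_circle_3pts",
    "fit_circles_batch",
    "fit_conic_lstsq",
    "fit_circle_lstsq",
]


@dataclass(frozen=True)
class ConicParams:
    """Reduced conic coefficients ``(b, c, d, e, f)`` with the x^2 term fixed at 1."""

    b: float
    c: float
    d: float
    e: float
    f: float

    @property
    def discriminant(self) -> float:
        return self.b * self.b - self.c

    def is_ellipse(self) -> bool:
        return self.discriminant < 0.0

    def as_array(self) -> np.ndarray:
        return np.array([self.b, self.c, self.d, self.e, self.f], dtype=float)

    def evaluate(self, x, y):
        """Value of the conic polynomial at (x, y)."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        return (
            x * x
            + 2.0 * self.b * x * y
            + self.c * y * y
            + 2.0 * self.d * x
            + 2.0 * self.e * y
            + self.f
        )

    def normalized_residual(self, x, y):
        """Scale-invariant algebraic residual of (x, y) against the conic.

        ``|Q(x, y)|`` divided by the product of the coefficient-vector norm and
        the monomial-vector norm, so exact incidence gives ~machine epsilon
        regardless of the pixel magnitude of the coordinates.
        """
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        coef = np.array([1.0, 2 * self.b, self.c, 2 * self.d, 2 * self.e, self.f])
        mono = np.stack(
            [x * x, x * y, y * y, x, y, np.ones_like(x)], axis=-1
        )
        denom = np.linalg.norm(coef) * np.linalg.norm(mono, axis=-1)
        return np.abs(self.evaluate(x, y)) / denom

    def to_ellipse(self) -> "Ellipse":
        """Geometric (center / semi-axes / orientation) form.

        Raises ``ValueError`` when the conic is not a real ellipse.
        """
        if not self.is_ellipse():
            raise ValueError("conic is not an ellipse (discriminant >= 0)")
        m = np.array([[1.0, self.b], [self.b, self.c]])
        center = np.linalg.solve(m, [-self.d, -self.e])
        cx, cy = float(center[0]), float(center[1])
        q0 = float(self.evaluate(cx, cy))
        if q0 >= 0.0:
            raise ValueError("conic is an imaginary/degenerate ellipse")
        evals, evecs = np.linalg.eigh(m)
        # ascending eigenvalues: smaller eigenvalue -> major axis
        a = math.sqrt(-q0 / evals[0])
        b_ax = math.sqrt(-q0 / evals[1])
        theta = math.atan2(evecs[1, 0], evecs[0, 0]) % math.pi
        return Ellipse(cx, cy, a, b_ax, theta)


@dataclass(frozen=True)
class Ellipse:
    """Ellipse with center ``(cx, cy)``, semi-axes ``a >= b`` and orientation theta."""

    cx: float
    cy: float
    a: float
    b: float
    theta: float = 0.0

    def __post_init__(self):
        if not (self.a > 0 and self.b > 0):
            raise ValueError(f"semi-axes must be positive, got a={self.a}, b={self.b}")
        if self.b > self.a:
            a, b = self.b, self.a
            object.__setattr__(self, "a", a)
            object.__setattr__(self, "b", b)
            object.__setattr__(self, "theta", (self.theta + math.pi / 2) % math.pi)
        else:
            object.__setattr__(self, "theta", self.theta % math.pi)

    @property
    def center(self) -> tuple[float, float]:
        return (self.cx, self.cy)

    def to_conic(self) -> ConicParams:
        ct, st = math.cos(self.theta), math.sin(self.theta)
        ia2, ib2 = 1.0 / self.a**2, 1.0 / self.b**2
        a0 = ct * ct * ia2 + st * st * ib2
        b0 = ct * st * (ia2 - ib2)
        c0 = st * st * ia2 + ct * ct * ib2
        d0 = -(a0 * self.cx + b0 * self.cy)
        e0 = -(b0 * self.cx + c0 * self.cy)
        f0 = (
            a0 * self.cx**2
            + 2 * b0 * self.cx * self.cy
            + c0 * self.cy**2
            - 1.0
        )
        return ConicParams(b0 / a0, c0 / a0, d0 / a0, e0 / a0, f0 / a0)

    def boundary_points(self, n: int = 360, jitter_rng=None) -> np.ndarray:
        """``n`` points on the boundary, uniformly spaced in parametric angle."""
        if jitter_rng is None:
            t = np.linspace(0.0, 2 * math.pi, n, endpoint=False)
        else:
            t = np.sort(jitter_rng.uniform(0.0, 2 * math.pi, size=n))
        ct, st = math.cos(self.theta), math.sin(self.theta)
        ex = self.a * np.cos(t)
        ey = self.b * np.sin(t)
        x = self.cx + ex * ct - ey * st
        y = self.cy + ex * st + ey * ct
        return np.stack([x, y], axis=1)

    def normalized_radius(self, points: np.ndarray) -> np.ndarray:
        """sqrt((x'/a)^2 + (y'/b)^2) in the ellipse frame; 1 on the boundary."""
        p = np.atleast_2d(np.asarray(points, dtype=float))
        ct, st = math.cos(self.theta), math.sin(self.theta)
        dx = p[:, 0] - self.cx
        dy = p[:, 1] - self.cy
        xp = dx * ct + dy * st
        yp = -dx * st + dy * ct
        return np.sqrt((xp / self.a) ** 2 + (yp / self.b) ** 2)

    def contains(self, points: np.ndarray, tol: float = 1e-9) -> np.ndarray:
        return self.normalized_radius(points) <= 1.0 + tol

    def approx_distance(self, points: np.ndarray) -> np.ndarray:
        """First-order point-to-boundary distance |Q(p)| / |grad Q(p)|."""
        p = np.atleast_2d(np.asarray(points, dtype=float))
        conic = self.to_conic()
        q = conic.evaluate(p[:, 0], p[:, 1])
        gx = 2 * p[:, 0] + 2 * conic.b * p[:, 1] + 2 * conic.d
        gy = 2 * conic.b * p[:, 0] + 2 * conic.c * p[:, 1] + 2 * conic.e
        grad = np.hypot(gx, gy)
        grad = np.where(grad < 1e-12, 1e-12, grad)
        return np.abs(q) / grad

    def scaled(self, factor: float) -> "Ellipse":
        return Ellipse(self.cx, self.cy, self.a * factor, self.b * factor, self.theta)


@dataclass(frozen=True)
class Circle:
    cx: float
    cy: float
    r: float

    def __post_init__(self):
        if not self.r > 0:
            raise ValueError(f"radius must be positive, got {self.r}")

    def to_ellipse(self) -> Ellipse:
        return Ellipse(self.cx, self.cy, self.r, self.r, 0.0)


@dataclass(frozen=True)
class BoundingBox:
    """Axis-aligned box, top-left (x, y), size (w, h), 0-based pixels."""

    x: float
    y: float
    w: float
    h: float

    def __post_init__(self):
        if not (self.w > 0 and self.h > 0):
            raise ValueError(f"box size must be positive, got w={self.w}, h={self.h}")

    @property
    def area(self) -> float:
        return self.w * self.h

    @property
    def cx(self) -> float:
        return self.x + self.w / 2.0

    @property
    def cy(self) -> float:
        return self.y + self.h / 2.0

    @property
    def x2(self) -> float:
        return self.x + self.w

    @property
    def y2(self) -> float:
        return self.y + self.h

    def intersection_area(self, other: "BoundingBox") -> float:
        iw = min(self.x2, other.x2) - max(self.x, other.x)
        ih = min(self.y2, other.y2) - max(self.y, other.y)
        if iw <= 0 or ih <= 0:
            return 0.0
        return iw * ih

    def overlap(self, other: "BoundingBox") -> float:
        """Intersection over union (used internally by the tracker's experts)."""
        inter = self.intersection_area(other)
        union = self.area + other.area - inter
        return inter / union if union > 0 else 0.0

    def inside(self, width: int, height: int) -> bool:
        return self.x >= 0 and self.y >= 0 and self.x2 <= width and self.y2 <= height

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.x, self.y, self.w, self.h)


def _normalizer(points: np.ndarray):
    """Similarity transform shifting to the centroid and scaling to RMS sqrt(2)."""
    pts = np.asarray(points, dtype=float)
    t = pts.mean(axis=0)
    rms = np.sqrt(((pts - t) ** 2).sum(axis=1).mean())
    s = math.sqrt(2.0) / rms if rms > 0 else 1.0
    return t, s


def _conic_from_matrix(m: np.ndarray) -> ConicParams | None:
    if abs(m[0, 0]) < 1e-300:
        return None
    m = m / m[0, 0]
    return ConicParams(m[0, 1], m[1, 1], m[0, 2], m[1, 2], m[2, 2])


def _denormalize_conic(theta: np.ndarray, t: np.ndarray, s: float) -> ConicParams | None:
    """Map reduced conic fitted in normalized coords back to pixel coords."""
    b, c, d, e, f = theta
    m_n = np.array([[1.0, b, d], [b, c, e], [d, e, f]])
    h = np.array([[s, 0.0, -s * t[0]], [0.0, s, -s * t[1]], [0.0, 0.0, 1.0]])
    return _conic_from_matrix(h.T @ m_n @ h)


def fit_conic_5pts(points: np.ndarray) -> ConicParams | None:
    """Exact conic through five distinct points.

    Solves the 5x5 linear system of the reduced conic in centered/scaled
    coordinates for conditioning.  Returns ``None`` for degenerate
    configurations (collinear or otherwise rank-deficient).
    """
    pts = np.asarray(points, dtype=float)
    if pts.shape != (5, 2):
        raise ValueError(f"expected five 2-D points, got shape {pts.shape}")
    if len(np.unique(pts, axis=0)) < 5:
        raise ValueError("points must be distinct")
    t, s = _normalizer(pts)
    p = (pts - t) * s
    x, y = p[:, 0], p[:, 1]
    a_mat = np.stack([2 * x * y, y * y, 2 * x, 2 * y, np.ones(5)], axis=1)
    rhs = -x * x
    if abs(np.linalg.det(a_mat)) < 1e-9:
        return None
    theta = np.linalg.solve(a_mat, rhs)
    return _denormalize_conic(theta, t, s)


def fit_conics_batch(groups: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized :func:`fit_conic_5pts` over ``(n, 5, 2)`` point groups.

    Returns ``(params, valid)`` where ``params`` is ``(n, 5)`` rows of
    ``(b, c, d, e, f)`` in pixel coordinates and ``valid`` marks rows where the
    5-point system was nonsingular.
    """
    g = np.asarray(groups, dtype=float)
    n = g.shape[0]
    t = g.mean(axis=1, keepdims=True)
    rms = np.sqrt(((g - t) ** 2).sum(axis=2).mean(axis=1))
    s = np.where(rms > 0, math.sqrt(2.0) / np.maximum(rms, 1e-12), 1.0)
    p = (g - t) * s[:, None, None]
    x, y = p[..., 0], p[..., 1]
    a_mat = np.stack(
        [2 * x * y, y * y, 2 * x, 2 * y, np.ones_like(x)], axis=2
    )
    rhs = -x * x
    det = np.linalg.det(a_mat)
    valid = np.abs(det) > 1e-9
    theta = np.zeros((n, 5))
    if valid.any():
        theta[valid] = np.linalg.solve(a_mat[valid], rhs[valid][..., None])[..., 0]
    # denormalize: M = H^T Mn H per group
    b, c, d, e, f = theta.T
    ones = np.ones(n)
    m_n = np.empty((n, 3, 3))
    m_n[:, 0, 0] = ones
    m_n[:, 0, 1] = m_n[:, 1, 0] = b
    m_n[:, 1, 1] = c
    m_n[:, 0, 2] = m_n[:, 2, 0] = d
    m_n[:, 1, 2] = m_n[:, 2, 1] = e
    m_n[:, 2, 2] = f
    h = np.zeros((n, 3, 3))
    h[:, 0, 0] = s
    h[:, 1, 1] = s
    h[:, 0, 2] = -s * t[:, 0, 0]
    h[:, 1, 2] = -s * t[:, 0, 1]
    h[:, 2, 2] = 1.0
    m = np.einsum("nji,njk,nkl->nil", h, m_n, h)
    a00 = m[:, 0, 0]
    valid &= np.abs(a00) > 1e-300
    a00 = np.where(valid, a00, 1.0)
    params = np.stack(
        [m[:, 0, 1], m[:, 1, 1], m[:, 0, 2], m[:, 1, 2], m[:, 2, 2]], axis=1
    ) / a00[:, None]
    return params, valid


def fit_circle_3pts(points: np.ndarray) -> Circle | None:
    """Circumscribed circle of three distinct points; ``None`` when collinear."""
    pts = np.asarray(points, dtype=float)
    if pts.shape != (3, 2):
        raise ValueError(f"expected three 2-D points, got shape {pts.shape}")
    if len(np.unique(pts, axis=0)) < 3:
        raise ValueError("points must be distinct")
    params, valid = fit_circles_batch(pts[None])
    if not valid[0]:
        return None
    cx, cy, r = params[0]
    return Circle(float(cx), float(cy), float(r))


def fit_circles_batch(groups: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized circumcircles of ``(n, 3, 2)`` point triples.

    Returns ``(params, valid)``, ``params`` rows ``(cx, cy, r)``.
    """
    g = np.asarray(groups, dtype=float)
    p0, p1, p2 = g[:, 0], g[:, 1], g[:, 2]
    # circumcenter from perpendicular-bisector linear system
    ax = p1 - p0
    bx = p2 - p0
    d = 2.0 * (ax[:, 0] * bx[:, 1] - ax[:, 1] * bx[:, 0])
    scale = np.maximum(
        np.linalg.norm(ax, axis=1) * np.linalg.norm(bx, axis=1), 1e-12
    )
    valid = np.abs(d) > 1e-9 * scale
    d = np.where(valid, d, 1.0)
    a2 = (ax**2).sum(axis=1)
    b2 = (bx**2).sum(axis=1)
    ux = (bx[:, 1] * a2 - ax[:, 1] * b2) / d
    uy = (ax[:, 0] * b2 - bx[:, 0] * a2) / d
    cx = p0[:, 0] + ux
    cy = p0[:, 1] + uy
    r = np.hypot(ux, uy)
    valid &= r > 0
    return np.stack([cx, cy, r], axis=1), valid


def fit_conic_lstsq(points: np.ndarray) -> ConicParams | None:
    """Least-squares conic over >= 5 points (SVD null vector of the design matrix).

    Used to refine accumulator peaks over their inlier sets; algebraic
    (gradient-unweighted) but computed in normalized coordinates.
    """
    pts = np.asarray(points, dtype=float)
    if pts.shape[0] < 5:
        return None
    t, s = _normalizer(pts)
    p = (pts - t) * s
    x, y = p[:, 0], p[:, 1]
    design = np.stack(
        [x * x, 2 * x * y, y * y, 2 * x, 2 * y, np.ones_like(x)], axis=1
    )
    _, _, vt = np.linalg.svd(design, full_matrices=False)
    coef = vt[-1]
    if abs(coef[0]) < 1e-12:
        return None
    coef = coef / coef[0]
    return _denormalize_conic(coef[1:], t, s)


def fit_circle_lstsq(points: np.ndarray) -> Circle | None:
    """Algebraic (Kasa) least-squares circle over >= 3 points."""
    pts = np.asarray(points, dtype=float)
    if pts.shape[0] < 3:
        return None
    x, y = pts[:, 0], pts[:, 1]
    a_mat = np.stack([2 * x, 2 * y, np.ones_like(x)], axis=1)
    rhs = x * x + y * y
    sol, _, rank, _ = np.linalg.lstsq(a_mat, rhs, rcond=None)
    if rank < 3:
        return None
    cx, cy, c0 = sol
    r2 = c0 + cx * cx + cy * cy
    if r2 <= 0:
        return None
    return Circle(float(cx), float(cy), float(math.sqrt(r2)))
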