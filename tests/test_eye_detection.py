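"""Randomized-Hough eye detection: preprocessing, sampling, detection, cascade."""

import numpy as np
import pytest

from vebird.eye_detection import (
    EdgeConfig,
    RhtConfig,
    detect_circle_rht,
    detect_ellipse_rht,
    detect_eye,
    detection_correct,
    preprocess_frame,
    sample_group,
    sample_groups,
)
from vebird.geometry import Ellipse
from vebird.synthetic import EyeImageSpec, generate_eye_image


class TestPreprocess:
    def test_constant_image_has_no_edges(self):
        assert preprocess_frame(np.full((64, 64), 0.5)).shape == (0, 2)
        assert preprocess_frame(np.full((64, 64, 3), 128, dtype=np.uint8)).shape == (0, 2)

    def test_empty_image_rejected(self):
        with pytest.raises(ValueError):
            preprocess_frame(np.empty((0, 0)))

    def test_binary_edge_image_retains_contour_drops_noise(self, noisy_ellipse_sample):
        s = noisy_ellipse_sample
        pts = preprocess_frame(s.edge_image)
        got = set(map(tuple, pts))
        contour = set(map(tuple, s.contour_points))
        assert len(got & contour) / len(contour) >= 0.9
        noise = set(map(tuple, s.noise_points)) - contour
        assert len(got & noise) / max(len(noise), 1) < 0.5

    def test_points_inside_image_bounds(self, noisy_ellipse_sample):
        pts = preprocess_frame(noisy_ellipse_sample.edge_image)
        h, w = noisy_ellipse_sample.edge_image.shape
        assert (pts[:, 0] >= 0).all() and (pts[:, 0] < w).all()
        assert (pts[:, 1] >= 0).all() and (pts[:, 1] < h).all()

    def test_gray_image_edge_detection_finds_disc_boundary(self):
        yy, xx = np.mgrid[0:128, 0:128]
        img = np.where(np.hypot(xx - 64, yy - 64) <= 40, 0.2, 0.8)
        pts = preprocess_frame(img, EdgeConfig(min_component=10))
        assert len(pts) > 100
        r = np.hypot(pts[:, 0] - 64, pts[:, 1] - 64)
        assert np.abs(r - 40).max() < 4


class TestSampling:
    def test_zero_distance_reduces_to_plain_sampling(self, rng):
        pts = rng.uniform(0, 100, size=(30, 2))
        g = sample_group(pts, 5, 0.0, rng)
        assert g.shape == (5, 2)
        assert len(np.unique(g, axis=0)) == 5

    def test_infeasible_cluster_rejected(self, rng):
        pts = rng.uniform(0, 2, size=(20, 2))
        assert sample_group(pts, 5, 10.0, rng, max_attempts=50) is None

    def test_all_sampled_groups_satisfy_pairwise_constraint(self, rng):
        pts = rng.uniform(0, 200, size=(150, 2))
        idx = sample_groups(pts, 5, 10_000, 15.0, rng)
        assert idx.shape[0] == 10_000
        for g in pts[idx[rng.choice(10_000, 500, replace=False)]]:
            d = np.linalg.norm(g[:, None] - g[None, :], axis=-1)
            assert d[np.triu_indices(5, 1)].min() >= 15.0


class TestEllipseDetection:
    def test_noiseless_contour_recovered(self):
        truth = Ellipse(128.0, 128.0, 60.0, 40.0, 0.3)
        s = generate_eye_image(
            EyeImageSpec(iris_ellipse=truth, noise_fraction=0.0, seed=11)
        )
        det = detect_ellipse_rht(s.points.astype(float), RhtConfig(seed=1))
        assert det is not None
        assert abs(det.cx - truth.cx) < 2 and abs(det.cy - truth.cy) < 2
        assert abs(det.a - truth.a) / truth.a < 0.05
        assert abs(det.b - truth.b) / truth.b < 0.05

    def test_pure_noise_returns_none(self, rng):
        pts = np.stack([rng.integers(0, 256, 300), rng.integers(0, 256, 300)], 1).astype(float)
        assert detect_ellipse_rht(pts, RhtConfig(seed=2, vote_threshold=60)) is None

    def test_seeded_determinism(self, noisy_ellipse_sample):
        pts = noisy_ellipse_sample.points.astype(float)
        a = detect_ellipse_rht(pts, RhtConfig(seed=5))
        b = detect_ellipse_rht(pts, RhtConfig(seed=5))
        assert a == b

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            detect_ellipse_rht(np.zeros((4, 2)), RhtConfig())


class TestCircleDetection:
    def test_noiseless_circle_radius_recovered(self):
        s = generate_eye_image(
            EyeImageSpec(
                iris_ellipse=Ellipse(128, 128, 50, 50, 0.0), noise_fraction=0.0, seed=12
            )
        )
        det = detect_circle_rht(s.points.astype(float), RhtConfig(seed=3))
        assert det is not None and abs(det.r - 50) < 2

    def test_elongated_ellipse_rejected_by_circle_stage(self):
        s = generate_eye_image(
            EyeImageSpec(
                iris_ellipse=Ellipse(128, 128, 70, 35, 0.4), noise_fraction=0.0, seed=13
            )
        )
        assert detect_circle_rht(s.points.astype(float), RhtConfig(seed=3)) is None

    def test_seeded_determinism(self, noisy_circle_sample):
        pts = noisy_circle_sample.points.astype(float)
        assert detect_circle_rht(pts, RhtConfig(seed=4)) == detect_circle_rht(
            pts, RhtConfig(seed=4)
        )


class TestCascade:
    def test_circular_iris_resolved_by_circle_stage(self, noisy_circle_sample):
        res = detect_eye(noisy_circle_sample.edge_image, RhtConfig(seed=6))
        assert res.stage == "circle"
        assert res.circle_attempted and not res.ellipse_attempted
        assert detection_correct(
            res.ellipse, noisy_circle_sample.iris, noisy_circle_sample.limbus
        )

    def test_elliptical_iris_falls_through_to_ellipse_stage(self, noisy_ellipse_sample):
        res = detect_eye(noisy_ellipse_sample.edge_image, RhtConfig(seed=6))
        assert res.stage == "ellipse"
        assert res.circle_attempted and res.ellipse_attempted
        assert detection_correct(
            res.ellipse, noisy_ellipse_sample.iris, noisy_ellipse_sample.limbus
        )

    def test_blank_frame_yields_none(self):
        res = detect_eye(np.zeros((128, 128), dtype=np.uint8), RhtConfig(seed=1))
        assert res.ellipse is None and res.stage is None


class TestDetectionCorrect:
    IRIS = Ellipse(128.0, 128.0, 60.0, 45.0, 0.2)
    LIMBUS = Ellipse(128.0, 128.0, 78.0, 58.5, 0.2)

    def test_self_containment(self):
        assert detection_correct(self.IRIS, self.IRIS, self.LIMBUS)

    def test_escaping_limbus_fails(self):
        assert not detection_correct(self.LIMBUS.scaled(1.5), self.IRIS, self.LIMBUS)

    def test_too_small_fails(self):
        assert not detection_correct(self.IRIS.scaled(0.8), self.IRIS, self.LIMBUS)

    def test_midway_ellipse_accepted_and_matches_raster_oracle(self):
        mid = Ellipse(128.0, 128.0, 69.0, 51.75, 0.2)
        assert detection_correct(mid, self.IRIS, self.LIMBUS)
        # dense rasterization oracle: pixel sets must nest iris < mid < limbus
        yy, xx = np.mgrid[0:256, 0:256]
        pts = np.stack([xx.ravel(), yy.ravel()], 1)
        inside_iris = self.IRIS.contains(pts)
        inside_mid = mid.contains(pts)
        inside_limbus = self.LIMBUS.contains(pts)
        assert not (inside_iris & ~inside_mid).any()
        assert not (inside_mid & ~inside_limbus).any()
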