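"""Tissue ROI geometry, color feature vector, cascade and KNN baseline."""

import numpy as np
import pytest

from vebird.geometry import BoundingBox, Ellipse
from vebird.grading import (
    GradingConfig,
    extract_features,
    extract_tissue_roi,
    grade,
    knn_baseline,
    train_cascade,
)
from vebird.synthetic import TissueColorModel, generate_tissue_patches

FAST_CONFIG = GradingConfig(
    c_grid=(1.0, 64.0), gamma_grid=(2.0**-6, 2.0**-2), cv_folds=3, seed=0
)


class TestTissueRoi:
    EYE = Ellipse(120.0, 90.0, 70.0, 70.0, 0.0)

    def test_roi_center_between_tip_and_eye_center(self):
        frame = np.zeros((180, 240, 3), dtype=np.uint8)
        probe = BoundingBox(60.0, 80.0, 30.0, 16.0)  # left of center, pointing right
        patch = extract_tissue_roi(frame, probe, self.EYE)
        roi = patch.source_roi
        tip_x = probe.x2  # right edge nearest the eye center
        assert tip_x < roi.cx < self.EYE.cx + 1

    def test_degenerate_centered_probe_breaks_tie_upward(self):
        frame = np.zeros((180, 240, 3), dtype=np.uint8)
        probe = BoundingBox(105.0, 82.0, 30.0, 16.0)  # centered on the eye
        patch = extract_tissue_roi(frame, probe, self.EYE)
        roi = patch.source_roi
        assert roi.cy < probe.y  # placed above the box (toward -y)
        assert abs(roi.cx - probe.cx) < 1.5

    def test_known_tissue_color_recovered_at_tip(self):
        frame = np.full((180, 240, 3), (190, 150, 40), dtype=np.uint8)
        probe = BoundingBox(60.0, 80.0, 30.0, 16.0)
        patch = extract_tissue_roi(frame, probe, self.EYE)
        assert np.abs(patch.pixels.reshape(-1, 3).mean(0) - (190, 150, 40)).max() < 1

    def test_roi_outside_eye_rejected(self):
        frame = np.zeros((180, 240, 3), dtype=np.uint8)
        probe = BoundingBox(200.0, 150.0, 30.0, 16.0)
        small_eye = Ellipse(60.0, 45.0, 25.0, 25.0, 0.0)
        with pytest.raises(ValueError):
            extract_tissue_roi(frame, probe, small_eye)


class TestFeatures:
    def test_uniform_patch_all_triples_equal(self):
        patch = np.full((32, 32, 3), (51, 102, 204), dtype=np.uint8)
        f = extract_features(patch)
        assert f.shape == (3264,)
        triples = f[: 3 * 1024].reshape(-1, 3)
        expected = np.array([51, 102, 204]) / 255.0
        assert np.allclose(triples, expected)
        assert np.allclose(f[3 * 1024 :].reshape(-1, 3), expected)

    def test_half_black_half_white_cell_means_exact(self):
        patch = np.zeros((32, 32, 3), dtype=np.uint8)
        patch[:, 16:] = 255
        f = extract_features(patch)
        means = f[3 * 1024 :].reshape(8, 8, 3)
        assert (means[:, :4] == 0.0).all()
        assert (means[:, 4:] == 1.0).all()

    def test_cell_means_match_bruteforce_oracle(self, rng):
        patch = rng.integers(0, 256, size=(32, 32, 3), dtype=np.uint8)
        f = extract_features(patch)
        means = f[3 * 1024 :].reshape(8, 8, 3)
        for i in range(8):
            for j in range(8):
                block = patch[4 * i : 4 * i + 4, 4 * j : 4 * j + 4] / 255.0
                assert means[i, j] == pytest.approx(block.mean(axis=(0, 1)), abs=1e-12)

    def test_pixel_block_is_row_major(self, rng):
        patch = rng.integers(0, 256, size=(32, 32, 3), dtype=np.uint8)
        f = extract_features(patch)
        assert f[3 * 35 : 3 * 36] == pytest.approx(patch[1, 3] / 255.0)  # pixel index 35

    def test_means_only_mode_and_bad_shape(self):
        patch = np.zeros((32, 32, 3), dtype=np.uint8)
        assert extract_features(patch, means_only=True).shape == (192,)
        with pytest.raises(ValueError):
            extract_features(np.zeros((16, 16, 3), dtype=np.uint8))


class TestCascade:
    def test_zero_noise_set_fully_separable_and_bijective(self, clean_patch_set):
        c = train_cascade(clean_patch_set.patches, clean_patch_set.labels, FAST_CONFIG)
        assert c.cv_scores["stage1_cv"] == 1.0
        assert c.cv_scores["stage2_cv"] == 1.0
        preds = np.array([grade(p, c) for p in clean_patch_set.patches])
        assert (preds == clean_patch_set.labels).all()

    def test_normal_patch_short_circuits_stage2(self, clean_patch_set):
        c = train_cascade(clean_patch_set.patches, clean_patch_set.labels, FAST_CONFIG)
        c.n_stage2_calls = 0
        normal = clean_patch_set.patches[clean_patch_set.labels == 0][0]
        assert grade(normal, c) == 0
        assert c.n_stage2_calls == 0
        hard = clean_patch_set.patches[clean_patch_set.labels == 5][0]
        assert grade(hard, c) == 5
        assert c.n_stage2_calls == 1

    def test_table_colors_map_to_expected_grades(self, clean_patch_set):
        c = train_cascade(clean_patch_set.patches, clean_patch_set.labels, FAST_CONFIG)
        dark_yellow = np.full((32, 32, 3), (190, 150, 40), dtype=np.uint8)
        assert grade(dark_yellow, c) == 3
        dark_brown = np.full((32, 32, 3), (70, 50, 30), dtype=np.uint8)
        assert grade(dark_brown, c) == 5

    def test_missing_class_rejected(self, clean_patch_set):
        mask = clean_patch_set.labels != 2
        with pytest.raises(ValueError, match="2"):
            train_cascade(
                clean_patch_set.patches[mask], clean_patch_set.labels[mask], FAST_CONFIG
            )

    def test_training_deterministic_given_seed(self, noisy_patch_set):
        a = train_cascade(noisy_patch_set.patches, noisy_patch_set.labels, FAST_CONFIG)
        b = train_cascade(noisy_patch_set.patches, noisy_patch_set.labels, FAST_CONFIG)
        assert a.stage1.C == b.stage1.C and a.stage1.gamma == b.stage1.gamma
        assert a.stage2.C == b.stage2.C and a.stage2.gamma == b.stage2.gamma

    def test_noisy_set_generalizes(self, noisy_patch_set):
        c = train_cascade(noisy_patch_set.patches, noisy_patch_set.labels, FAST_CONFIG)
        test = generate_tissue_patches(TissueColorModel(noise_scale=10.0, seed=99), 10)
        preds = np.array([grade(p, c) for p in test.patches])
        assert (preds == test.labels).mean() >= 0.95


class TestKnn:
    def test_identical_query_k1(self, clean_patch_set):
        feats = np.stack([extract_features(p) for p in clean_patch_set.patches])
        pred = knn_baseline(feats, clean_patch_set.labels, feats[7], k=1)
        assert pred[0] == clean_patch_set.labels[7]

    def test_majority_vote(self):
        x = np.array([[0.0], [0.1], [0.2], [5.0], [5.1]])
        y = np.array([2, 2, 2, 4, 4])
        assert knn_baseline(x, y, np.array([0.15]), k=5)[0] == 2

    def test_tie_breaks_by_mean_distance(self):
        x = np.array([[0.0], [1.0], [10.0], [11.5]])
        y = np.array([1, 1, 3, 3])
        # query at 5.5: labels 1 and 3 tie 2-2; label 1 has the smaller mean distance
        assert knn_baseline(x, y, np.array([5.2]), k=4)[0] == 1

    def test_matches_sklearn_on_unambiguous_queries(self, rng):
        from sklearn.neighbors import KNeighborsClassifier

        x = rng.normal(size=(120, 8))
        y = rng.integers(0, 3, size=120)
        q = rng.normal(size=(100, 8))
        sk = KNeighborsClassifier(n_neighbors=5).fit(x, y)
        mine = knn_baseline(x, y, q, k=5)
        theirs = sk.predict(q)
        # tie-breaking conventions differ, so compare only strict majorities
        _, idx = sk.kneighbors(q)
        strict = np.array(
            [np.bincount(y[row]).max() > 2 for row in idx]
        )
        assert strict.any()
        assert (mine[strict] == theirs[strict]).all()

    def test_empty_training_set_rejected(self):
        with pytest.raises(ValueError):
            knn_baseline(np.empty((0, 3)), np.empty(0, dtype=int), np.zeros(3), k=1)
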