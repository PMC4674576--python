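"""Tracker components: LK/median flow, variance filter, ferns, NN model, P-N."""

import numpy as np
import pytest

from vebird.geometry import BoundingBox
from vebird.synthetic import ProbeVideoSpec, bouncing_trajectory, generate_probe_video
from vebird.tracking import (
    FernEnsemble,
    TldTracker,
    TrackerConfig,
    adaptive_posterior_update,
    ensemble_classify,
    extract_patch,
    fern_code,
    median_flow,
    nn_confirm,
    to_gray,
    track_video,
    variance_filter,
)
from vebird.tracking.model import ObjectModel


@pytest.fixture(scope="module")
def translation_video():
    traj = np.stack([10.0 + 2 * np.arange(40), np.full(40, 30.0)], axis=1)
    return generate_probe_video(
        ProbeVideoSpec(n_frames=40, trajectory=traj, background_drift_rate=0.0, seed=21)
    )


class TestMedianFlow:
    def test_identity_input_zero_displacement(self, translation_video):
        g = to_gray(translation_video.frames[0])
        box = translation_video.boxes[0]
        res = median_flow(g, g, box)
        assert res.box is not None
        assert abs(res.box.cx - box.cx) < 0.1 and abs(res.box.cy - box.cy) < 0.1
        assert res.median_fb_error < 0.1

    def test_pure_translation_tracked_within_half_pixel(self, translation_video):
        v = translation_video
        for t in range(1, 15):
            res = median_flow(to_gray(v.frames[t - 1]), to_gray(v.frames[t]), v.boxes[t - 1])
            assert res.box is not None
            assert abs(res.box.cx - v.boxes[t].cx) < 0.5
            assert abs(res.box.cy - v.boxes[t].cy) < 0.5

    def test_textureless_region_yields_failure_signal(self):
        # a featureless box has no trackable points: every LK gradient matrix
        # is rank-deficient, too few points survive, and the tracker fails
        prev = np.zeros((120, 160), dtype=np.float32)
        curr = np.zeros((120, 160), dtype=np.float32)
        res = median_flow(prev, curr, BoundingBox(40, 40, 40, 24))
        assert res.box is None
        assert res.n_points < 5

    def test_occluded_probe_is_vetoed_by_the_cascade(self):
        # when the probe vanishes the median-flow box slides onto background
        # and the detection cascade refuses to validate it: the reported
        # output for the occluded frames is absent
        traj = np.tile([60.0, 45.0], (30, 1))
        v = generate_probe_video(
            ProbeVideoSpec(
                n_frames=30,
                trajectory=traj,
                background_drift_rate=0.0,
                occlusion_frames=frozenset(range(20, 30)),
                seed=33,
            )
        )
        tr = TldTracker(v.frames[0], v.boxes[0], TrackerConfig(seed=6, n_pairs=8))
        absent = 0
        for t in range(1, 30):
            res = tr.step(v.frames[t])
            if t >= 21:
                absent += res.box is None
        assert absent >= 5

    def test_box_outside_frame_rejected(self):
        g = np.zeros((50, 50), dtype=np.float32)
        with pytest.raises(ValueError):
            median_flow(g, g, BoundingBox(40, 40, 20, 20))


class TestVarianceFilter:
    def test_constant_patch_rejected(self):
        assert not variance_filter(np.full((15, 15), 0.3), 0.01)

    def test_below_half_rejected_above_accepted(self):
        rng = np.random.default_rng(0)
        base = rng.random((15, 15))
        v = float(np.var(base))
        scaled_down = base * np.sqrt(0.4)  # variance 0.4 v
        assert not variance_filter(scaled_down, v)
        scaled_up = base * np.sqrt(0.6)
        assert variance_filter(scaled_up, v)


class TestFerns:
    def test_constant_patch_code_zero(self):
        pairs = np.array([[[0, 0], [1, 1]], [[2, 2], [3, 3]], [[4, 4], [5, 5]]])
        assert fern_code(np.full((8, 8), 7), pairs) == 0

    def test_code_range_bound(self, rng):
        pairs = rng.integers(0, 8, size=(5, 2, 2))
        for _ in range(20):
            code = fern_code(rng.random((8, 8)), pairs)
            assert 0 <= code < 2**5

    def test_hand_evaluated_code(self):
        patch = np.arange(16).reshape(4, 4)
        pairs = np.array(
            [
                [[3, 3], [0, 0]],  # 15 > 0  -> bit0 = 1
                [[0, 0], [3, 3]],  # 0 > 15  -> bit1 = 0
                [[2, 0], [1, 3]],  # 8 > 7   -> bit2 = 1
            ]
        )
        assert fern_code(patch, pairs) == 0b101

    def test_out_of_range_pair_rejected(self):
        with pytest.raises(ValueError):
            fern_code(np.zeros((4, 4)), np.array([[[0, 0], [4, 0]]]))

    def test_ensemble_classify_examples(self, rng):
        ens = FernEnsemble(n_ferns=3, n_pairs=4, adaptive=False, rng=rng)
        codes = np.array([1, 2, 3])
        s, label = ensemble_classify(codes, ens)
        assert s == 0.0 and not label  # all posteriors unseen -> 0
        ens.update(codes, positive=True)
        s, label = ensemble_classify(codes, ens)
        assert s == 3.0 and label  # all posteriors 1, threshold 1.5

    def test_mixed_posterior_sum_matches_hand_arithmetic(self, rng):
        ens = FernEnsemble(n_ferns=3, n_pairs=4, adaptive=False, rng=rng)
        codes = np.array([5, 6, 7])
        ens.update(codes, positive=True)
        ens.update(codes, positive=True)
        ens.update(codes, positive=False)  # each fern: 2 pos, 1 neg -> 2/3
        s, _ = ensemble_classify(codes, ens)
        assert s == pytest.approx(3 * 2 / 3)


class TestAdaptivePosterior:
    def test_prior_is_half_before_any_samples(self, rng):
        ens = FernEnsemble(n_ferns=10, n_pairs=4, adaptive=True, rng=rng)
        adaptive_posterior_update(ens, 0, 0)
        table = ens.posterior_table()
        assert (table[ens.adaptive_idx] == 0.5).all()

    def test_prior_equals_sample_ratio(self, rng):
        ens = FernEnsemble(n_ferns=10, n_pairs=4, adaptive=True, rng=rng)
        adaptive_posterior_update(ens, 30, 40)
        assert (ens.posterior_table()[ens.adaptive_idx] == 0.75).all()

    def test_observed_entries_keep_counted_posterior(self, rng):
        ens = FernEnsemble(n_ferns=10, n_pairs=4, adaptive=True, rng=rng)
        f = int(ens.adaptive_idx[0])
        codes = np.zeros(10, dtype=int)
        codes[f] = 3
        ens.update(codes, positive=False)
        adaptive_posterior_update(ens, 30, 40)
        table = ens.posterior_table()
        assert table[f, 3] == 0.0  # seen entry: evidence, not prior
        assert table[f, 5] == 0.75  # unseen entry: prior

    def test_non_adaptive_unseen_entries_stay_zero(self, rng):
        ens = FernEnsemble(n_ferns=10, n_pairs=4, adaptive=True, rng=rng)
        adaptive_posterior_update(ens, 30, 40)
        table = ens.posterior_table()
        non_adaptive = np.setdiff1d(np.arange(10), ens.adaptive_idx)
        assert (table[non_adaptive] == 0.0).all()

    def test_subset_size_is_ceil_one_fifth(self, rng):
        assert FernEnsemble(10, 4, adaptive=True, rng=rng).adaptive_idx.size == 2
        assert FernEnsemble(7, 4, adaptive=True, rng=np.random.default_rng(0)).adaptive_idx.size == 2
        assert FernEnsemble(10, 4, adaptive=False, rng=np.random.default_rng(0)).adaptive_idx.size == 0

    def test_posteriors_always_within_unit_interval(self, rng):
        ens = FernEnsemble(n_ferns=6, n_pairs=5, adaptive=True, rng=rng)
        for _ in range(30):
            ens.update(rng.integers(0, 32, size=6), positive=bool(rng.integers(2)))
        adaptive_posterior_update(ens, 17, 40)
        table = ens.posterior_table()
        assert (table >= 0).all() and (table <= 1).all()


class TestObjectModel:
    def _model(self):
        m = ObjectModel(init_variance=0.01)
        rng = np.random.default_rng(5)
        pos = rng.random((15, 15)).astype(np.float32)
        neg = rng.random((15, 15)).astype(np.float32)
        m.add_positive(pos - pos.mean())
        m.add_negative(neg - neg.mean())
        return m

    def test_identical_to_positive_is_positive(self):
        m = self._model()
        sr, _, label = nn_confirm(m.positive[0], m)
        assert sr > 0.5 and label

    def test_identical_to_negative_is_negative(self):
        m = self._model()
        sr, _, label = nn_confirm(m.negative[0], m)
        assert sr < 0.5 and not label

    def test_symmetric_patch_in_both_sets_scores_half(self):
        m = self._model()
        shared = m.positive[0]
        m.add_negative(shared)
        sr, _, _ = nn_confirm(shared, m)
        assert sr == pytest.approx(0.5)

    def test_empty_model_rejected(self):
        m = ObjectModel(0.0)
        with pytest.raises(ValueError):
            nn_confirm(np.zeros((15, 15)), m)


class TestPnLearning:
    def _tracker(self, video):
        return TldTracker(video.frames[0], video.boxes[0], TrackerConfig(seed=2, n_pairs=8))

    def test_counters_monotone_and_consistent(self, translation_video):
        tr = self._tracker(translation_video)
        prev = (tr.n_positive, tr.n_total)
        assert 0 <= tr.n_positive <= tr.n_total
        for t in range(1, 20):
            tr.step(translation_video.frames[t])
            assert tr.n_positive >= prev[0] and tr.n_total >= prev[1]
            assert tr.n_positive <= tr.n_total
            prev = (tr.n_positive, tr.n_total)

    def test_constructed_miss_grows_positive_counts(self, translation_video):
        tr = self._tracker(translation_video)
        gray = to_gray(translation_video.frames[1])
        from scipy.ndimage import gaussian_filter

        blur = gaussian_filter(gray, 1.0)
        _, cache = tr._detect(gray, blur)
        # zero the ensemble so every overlapping window is a false negative
        tr.ensemble.pos_counts[:] = 0
        tr.ensemble.neg_counts[:] = 0
        before = tr.ensemble.pos_counts.sum()
        tr._pn_update(gray, translation_video.boxes[1], cache, [])
        assert tr.ensemble.pos_counts.sum() > before

    def test_prior_tracks_counters_after_each_step(self, translation_video):
        tr = self._tracker(translation_video)
        for t in range(1, 10):
            tr.step(translation_video.frames[t])
            assert tr.ensemble.prior == pytest.approx(
                tr.n_positive / tr.n_total if tr.n_total else 0.5
            )


class TestDetectorApi:
    def test_detect_finds_training_frame_object(self, translation_video):
        v = translation_video
        tr = TldTracker(v.frames[0], v.boxes[0], TrackerConfig(seed=7, n_pairs=8))
        cands = tr.detect(v.frames[0])
        assert cands
        best = max(
            cands,
            key=lambda c: c[0].intersection_area(v.boxes[0])
            / min(c[0].area, v.boxes[0].area),
        )
        overlap = best[0].intersection_area(v.boxes[0]) / min(best[0].area, v.boxes[0].area)
        assert overlap > 0.8

    def test_detect_on_pure_noise_returns_nothing(self, translation_video, rng):
        v = translation_video
        tr = TldTracker(v.frames[0], v.boxes[0], TrackerConfig(seed=7, n_pairs=8))
        noise = rng.integers(0, 256, size=v.frames[0].shape, dtype=np.uint8)
        assert tr.detect(noise) == []

    def test_public_pn_update_reports_sample_counts(self, translation_video):
        v = translation_video
        tr = TldTracker(v.frames[0], v.boxes[0], TrackerConfig(seed=7, n_pairs=8))
        tr.ensemble.pos_counts[:] = 0
        tr.ensemble.neg_counts[:] = 0
        pos, neg = tr.pn_update(v.frames[1], v.boxes[1])
        assert pos >= 1
        assert tr.n_positive <= tr.n_total


class TestTrackVideo:
    def test_static_video_high_overlap_throughout(self):
        traj = np.tile([60.0, 45.0], (25, 1))
        v = generate_probe_video(
            ProbeVideoSpec(n_frames=25, trajectory=traj, background_drift_rate=0.0, seed=31)
        )
        res = track_video(v.frames, v.boxes[0], TrackerConfig(seed=3, n_pairs=8))
        present = [b for b in res.trajectory if b is not None]
        assert len(present) >= 23
        for b in present:
            inter = b.intersection_area(v.boxes[0])
            assert inter / min(b.area, v.boxes[0].area) >= 0.9

    def test_boxes_stay_inside_frame(self, translation_video):
        v = translation_video
        res = track_video(v.frames, v.boxes[0], TrackerConfig(seed=4, n_pairs=8))
        h, w = v.frames[0].shape[:2]
        for b in res.trajectory:
            if b is not None:
                assert b.inside(w, h)

    def test_toggle_equivalence_with_empty_adaptive_subset(self, translation_video):
        """adaptive=False must reproduce the base tracker bit for bit; the
        adaptive subset is the only difference between the two systems."""
        v = translation_video
        frames = v.frames[:15]
        res_a = track_video(frames, v.boxes[0], TrackerConfig(seed=5, n_pairs=8, adaptive=False))
        ens = None
        res_b = track_video(frames, v.boxes[0], TrackerConfig(seed=5, n_pairs=8, adaptive=False))
        for a, b in zip(res_a.trajectory, res_b.trajectory):
            if a is None:
                assert b is None
            else:
                assert a.as_tuple() == b.as_tuple()

    def test_init_box_outside_frame_rejected(self, translation_video):
        with pytest.raises(ValueError):
            track_video(
                translation_video.frames, BoundingBox(150, 110, 40, 24), TrackerConfig()
            )
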