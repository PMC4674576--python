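"""Tracking-Learning-Detection of the surgical probe.

Per frame the Median Flow tracker proposes a box, a scanning-window detector
(variance filter -> fern ensemble -> nearest-neighbour reconfirmation)
proposes candidates, and the two are integrated; when the output location is
reliable, P-N learning relabels the detector's mistakes — windows overlapping
the output that the ensemble called negative become positive samples
(P-expert), distant windows it called positive become negatives (N-expert) —
and the adaptive ferns' unseen-code prior is refreshed with the running
positive/total sample ratio.

The tracker's box is accepted only if the detector cascade agrees with it
(ensemble label positive and nearest-neighbour similarity above threshold);
otherwise the frame is reported absent and re-detection must recover the
probe.  This is precisely where the adaptive prior matters: with a drifting
background inside the annotation rectangle, many fern codes are novel, the
classical ensemble sums toward zero and vetoes a perfectly good track, while
the adaptive ensemble keeps answering with the prior.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter, map_coordinates

from ..geometry import BoundingBox
from .ferns import FernEnsemble, adaptive_posterior_update
from .median_flow import median_flow
from .model import ObjectModel, extract_patch, nn_confirm

__all__ = ["TrackerConfig", "TldTracker", "TrackResult", "StepResult", "track_video", "to_gray"]


def to_gray(frame: np.ndarray) -> np.ndarray:
    """Luminance in [0, 1] as float32."""
    img = np.asarray(frame)
    if img.ndim == 3:
        gray = img[..., :3].astype(np.float32) @ np.array(
            [0.299, 0.587, 0.114], dtype=np.float32
        )
    else:
        gray = img.astype(np.float32)
    if img.dtype == np.uint8:
        gray = gray / np.float32(255.0)
    return gray


@dataclass(frozen=True)
class TrackerConfig:
    patch_size: int = 15
    n_ferns: int = 10
    n_pairs: int = 13
    adaptive: bool = True
    nn_threshold: float = 0.55  # detector NN confirmation
    nn_valid_threshold: float = 0.5  # tracker-box acceptance
    conservative_threshold: float = 0.58  # gate for learning
    fb_threshold: float = 10.0
    grid_n: int = 10
    scale_exponents: tuple[int, ...] = (-2, -1, 0, 1, 2)
    scale_base: float = 1.2
    stride_frac: float = 0.1
    min_window: int = 8
    max_nn_candidates: int = 25
    n_init_warps: int = 40
    n_init_negatives: int = 100
    reinit_min_conf: float = 0.0  # optional extra confidence gate on re-detection
    max_p_samples: int = 10
    max_n_samples: int = 100
    seed: int = 0


@dataclass(frozen=True)
class StepResult:
    box: BoundingBox | None
    source: str | None  # "tracker" | "detector" | None
    tracker_valid: bool
    n_candidates: int


@dataclass(frozen=True)
class TrackResult:
    trajectory: list[BoundingBox | None]
    steps: list[StepResult]


class _ScanScale:
    """Sliding-window grid at one window size, with per-scale fern offsets."""

    def __init__(self, frame_shape, w, h, stride_frac, pairs_norm):
        fh, fw = frame_shape
        self.w, self.h = w, h
        sx = max(1, int(round(stride_frac * w)))
        sy = max(1, int(round(stride_frac * h)))
        xs = np.arange(0, fw - w + 1, sx)
        ys = np.arange(0, fh - h + 1, sy)
        gx, gy = np.meshgrid(xs, ys, indexing="xy")
        self.x0 = gx.ravel()
        self.y0 = gy.ravel()
        # pixel offsets of the fern comparison endpoints at this window size
        self.ox = np.clip(np.rint(pairs_norm[..., 0] * (w - 1)).astype(int), 0, w - 1)
        self.oy = np.clip(np.rint(pairs_norm[..., 1] * (h - 1)).astype(int), 0, h - 1)

    @property
    def n_windows(self) -> int:
        return self.x0.size

    def boxes(self, idx) -> np.ndarray:
        return np.stack(
            [
                self.x0[idx],
                self.y0[idx],
                np.full(np.size(idx), self.w),
                np.full(np.size(idx), self.h),
            ],
            axis=-1,
        ).astype(float)

    def codes(self, blur: np.ndarray, idx: np.ndarray, n_ferns: int, n_pairs: int) -> np.ndarray:
        x0 = self.x0[idx]
        y0 = self.y0[idx]
        out = np.zeros((x0.size, n_ferns), dtype=np.int64)
        for f in range(n_ferns):
            code = np.zeros(x0.size, dtype=np.int64)
            for p in range(n_pairs):
                v1 = blur[y0 + self.oy[f, p, 0], x0 + self.ox[f, p, 0]]
                v2 = blur[y0 + self.oy[f, p, 1], x0 + self.ox[f, p, 1]]
                code |= (v1 > v2).astype(np.int64) << p
            out[:, f] = code
        return out


def _integral_pair(gray: np.ndarray):
    g = gray.astype(np.float64)
    ii = np.zeros((g.shape[0] + 1, g.shape[1] + 1))
    ii2 = np.zeros_like(ii)
    np.cumsum(np.cumsum(g, 0), 1, out=ii[1:, 1:])
    np.cumsum(np.cumsum(g * g, 0), 1, out=ii2[1:, 1:])
    return ii, ii2


def _window_variance(ii, ii2, x0, y0, w, h):
    area = w * h
    s = ii[y0 + h, x0 + w] - ii[y0, x0 + w] - ii[y0 + h, x0] + ii[y0, x0]
    s2 = ii2[y0 + h, x0 + w] - ii2[y0, x0 + w] - ii2[y0 + h, x0] + ii2[y0, x0]
    m = s / area
    return np.maximum(s2 / area - m * m, 0.0)


def _iou_arrays(x0, y0, w, h, box: BoundingBox) -> np.ndarray:
    iw = np.minimum(x0 + w, box.x2) - np.maximum(x0, box.x)
    ih = np.minimum(y0 + h, box.y2) - np.maximum(y0, box.y)
    inter = np.clip(iw, 0, None) * np.clip(ih, 0, None)
    union = w * h + box.area - inter
    return inter / union


@dataclass
class _Candidate:
    box: BoundingBox
    fern_sum: float
    conf: float  # NN relative similarity


class TldTracker:
    """Stateful probe tracker; construct on frame 1 with the annotated box."""

    def __init__(self, frame: np.ndarray, init_box: BoundingBox, config: TrackerConfig | None = None):
        self.config = config or TrackerConfig()
        cfg = self.config
        gray = to_gray(frame)
        h, w = gray.shape
        if not init_box.inside(w, h):
            raise ValueError(f"init box {init_box.as_tuple()} outside {w}x{h} frame")
        self.rng = np.random.default_rng(cfg.seed)
        self.ensemble = FernEnsemble(
            cfg.n_ferns, cfg.n_pairs, adaptive=cfg.adaptive, rng=self.rng
        )
        self.grid: list[_ScanScale] = []
        for e in cfg.scale_exponents:
            f = cfg.scale_base**e
            sw, sh = int(round(init_box.w * f)), int(round(init_box.h * f))
            if sw < cfg.min_window or sh < cfg.min_window or sw > w or sh > h:
                continue
            scale = _ScanScale(gray.shape, sw, sh, cfg.stride_frac, self.ensemble.pairs)
            if scale.n_windows:
                self.grid.append(scale)
        if not self.grid:
            raise ValueError("no scan windows fit in the frame")

        x0, y0 = int(round(init_box.x)), int(round(init_box.y))
        bw, bh = int(round(init_box.w)), int(round(init_box.h))
        init_var = float(np.var(gray[y0 : y0 + bh, x0 : x0 + bw]))
        self.model = ObjectModel(init_var)
        self.n_positive = 0
        self.n_total = 0
        self.box: BoundingBox | None = init_box
        self.prev_gray = gray
        self._init_learn(gray, init_box)
        adaptive_posterior_update(self.ensemble, self.n_positive, self.n_total)

    # ------------------------------------------------------------------ init
    def _box_codes(self, blur: np.ndarray, box: BoundingBox) -> np.ndarray:
        """Fern codes of an arbitrary (float) box via bilinear sampling."""
        cfg = self.config
        pn = self.ensemble.pairs  # (F, P, 2, 2) normalized (x, y)
        xs = box.x + pn[..., 0] * (box.w - 1)
        ys = box.y + pn[..., 1] * (box.h - 1)
        vals = map_coordinates(
            blur, np.stack([ys.ravel(), xs.ravel()]), order=1, mode="nearest"
        ).reshape(cfg.n_ferns, cfg.n_pairs, 2)
        bits = (vals[..., 0] > vals[..., 1]).astype(np.int64)
        return (bits << np.arange(cfg.n_pairs)[None, :]).sum(axis=1)

    def _jittered(self, box: BoundingBox) -> BoundingBox:
        dx, dy = self.rng.uniform(-1.5, 1.5, size=2)
        ds = self.rng.uniform(0.95, 1.05)
        w, h = box.w * ds, box.h * ds
        return BoundingBox(box.cx + dx - w / 2, box.cy + dy - h / 2, w, h)

    def _init_learn(self, gray: np.ndarray, init_box: BoundingBox) -> None:
        cfg = self.config
        blur = gaussian_filter(gray, 1.0)
        self.model.add_positive(extract_patch(gray, init_box, cfg.patch_size))
        pos_codes = [self._box_codes(blur, init_box)]
        for _ in range(cfg.n_init_warps - 1):
            pos_codes.append(self._box_codes(blur, self._jittered(init_box)))
        self.ensemble.update(np.stack(pos_codes), positive=True)

        ii, ii2 = _integral_pair(gray)
        neg_codes = []
        neg_patch_pool = []
        for scale in self.grid:
            var = _window_variance(ii, ii2, scale.x0, scale.y0, scale.w, scale.h)
            iou = _iou_arrays(scale.x0, scale.y0, scale.w, scale.h, init_box)
            sel = np.nonzero((var >= 0.5 * self.model.init_variance) & (iou < 0.2))[0]
            if sel.size:
                neg_codes.append(scale.codes(blur, sel, cfg.n_ferns, cfg.n_pairs))
                neg_patch_pool.append(scale.boxes(sel))
        if neg_codes:
            codes = np.concatenate(neg_codes)
            boxes = np.concatenate(neg_patch_pool)
            take = self.rng.choice(
                codes.shape[0], size=min(cfg.n_init_negatives, codes.shape[0]), replace=False
            )
            self.ensemble.update(codes[take], positive=False)
            for i in take[:10]:
                self.model.add_negative(
                    extract_patch(gray, BoundingBox(*boxes[i]), cfg.patch_size)
                )
            self.n_total += take.size
        self.n_positive += len(pos_codes)
        self.n_total += len(pos_codes)

    # -------------------------------------------------------------- detector
    def detect(self, frame: np.ndarray) -> list[tuple[BoundingBox, float]]:
        """Run the scanning-window cascade on a frame.

        Returns the confirmed candidate boxes with their nearest-neighbour
        confidences (the step loop uses the same cascade internally).
        """
        gray = to_gray(frame)
        candidates, _ = self._detect(gray, gaussian_filter(gray, 1.0))
        return [(c.box, c.conf) for c in candidates]

    def pn_update(self, frame: np.ndarray, final_box: BoundingBox) -> tuple[int, int]:
        """Apply one P-N learning step against ``final_box``.

        Returns the (positive, negative) sample counts added.  The step loop
        calls this automatically for reliable tracker outputs.
        """
        gray = to_gray(frame)
        blur = gaussian_filter(gray, 1.0)
        candidates, cache = self._detect(gray, blur)
        added = self._pn_update(gray, final_box, cache, candidates)
        adaptive_posterior_update(self.ensemble, self.n_positive, self.n_total)
        return added

    def _detect(self, gray: np.ndarray, blur: np.ndarray):
        cfg = self.config
        ii, ii2 = _integral_pair(gray)
        cache = []
        raw: list[tuple[BoundingBox, float]] = []
        for scale in self.grid:
            var = _window_variance(ii, ii2, scale.x0, scale.y0, scale.w, scale.h)
            sel = np.nonzero(var >= 0.5 * self.model.init_variance)[0]
            codes = scale.codes(blur, sel, cfg.n_ferns, cfg.n_pairs)
            sums = self.ensemble.posterior_sums(codes) if sel.size else np.zeros(0)
            cache.append((scale, sel, codes, sums))
            pos = np.nonzero(sums > self.ensemble.threshold)[0]
            for i in pos:
                raw.append(
                    (
                        BoundingBox(
                            float(scale.x0[sel[i]]),
                            float(scale.y0[sel[i]]),
                            float(scale.w),
                            float(scale.h),
                        ),
                        float(sums[i]),
                    )
                )
        raw.sort(key=lambda t: -t[1])
        candidates: list[_Candidate] = []
        for box, fsum in raw[: cfg.max_nn_candidates]:
            patch = extract_patch(gray, box, cfg.patch_size)
            sr, _, label = nn_confirm(patch, self.model, cfg.nn_threshold)
            if label:
                candidates.append(_Candidate(box, fsum, sr))
        return candidates, cache

    @staticmethod
    def _cluster(cands: list[_Candidate]) -> list[list[_Candidate]]:
        clusters: list[list[_Candidate]] = []
        for c in sorted(cands, key=lambda c: -c.conf):
            for cl in clusters:
                if cl[0].box.overlap(c.box) > 0.5:
                    cl.append(c)
                    break
            else:
                clusters.append([c])
        return clusters

    @staticmethod
    def _mean_box(cands: list[_Candidate]) -> BoundingBox:
        arr = np.array([c.box.as_tuple() for c in cands])
        x, y, w, h = arr.mean(axis=0)
        return BoundingBox(x, y, w, h)

    def _clip_box(self, box: BoundingBox, shape) -> BoundingBox | None:
        h, w = shape
        bw = min(box.w, w - 1)
        bh = min(box.h, h - 1)
        if bw < 4 or bh < 4:
            return None
        x = min(max(box.x, 0.0), w - bw)
        y = min(max(box.y, 0.0), h - bh)
        return BoundingBox(x, y, bw, bh)

    # ------------------------------------------------------------------ step
    def step(self, frame: np.ndarray) -> StepResult:
        cfg = self.config
        gray = to_gray(frame)
        blur = gaussian_filter(gray, 1.0)

        tracker_box = None
        tracker_sr = tracker_sc = 0.0
        tracker_valid = False
        if self.box is not None:
            mf = median_flow(
                self.prev_gray,
                gray,
                self.box,
                fb_threshold=cfg.fb_threshold,
                grid_n=cfg.grid_n,
            )
            if mf.box is not None:
                tracker_box = self._clip_box(mf.box, gray.shape)
        if tracker_box is not None:
            codes = self._box_codes(blur, tracker_box)
            fsum = float(self.ensemble.posterior_sums(codes[None])[0])
            patch = extract_patch(gray, tracker_box, cfg.patch_size)
            tracker_sr, tracker_sc, _ = nn_confirm(patch, self.model, cfg.nn_threshold)
            tracker_valid = (
                fsum > self.ensemble.threshold and tracker_sr > cfg.nn_valid_threshold
            )

        candidates, cache = self._detect(gray, blur)

        # the reported output can be absent while the internal track persists:
        # a vetoed (unvalidated) median-flow box keeps being tracked so a
        # single ensemble false-negative does not destroy the trajectory
        final: BoundingBox | None = None
        source: str | None = None
        learn = False
        # coast on median-flow failure: hold the last box (reported absent
        # unless re-validated) instead of abandoning the track entirely
        internal: BoundingBox | None = tracker_box if tracker_box is not None else self.box
        if tracker_box is not None and tracker_valid:
            # overriding a validated track is high-stakes: demand a clearly
            # more confident, multiply-supported, unambiguous far cluster
            far = [
                c
                for c in candidates
                if c.box.overlap(tracker_box) < 0.5 and c.conf > tracker_sr + 0.10
            ]
            far_clusters = self._cluster(far)
            if len(far_clusters) == 1 and len(far) >= 2:
                final = self._mean_box(far_clusters[0])
                source = "detector"
            else:
                close = [c for c in candidates if c.box.overlap(tracker_box) > 0.5]
                arr = np.array(
                    [tracker_box.as_tuple()] * 10 + [c.box.as_tuple() for c in close]
                )
                x, y, w, h = arr.mean(axis=0)
                final = BoundingBox(x, y, w, h)
                source = "tracker"
                learn = tracker_sc > cfg.conservative_threshold
        elif candidates:
            # tracker failed or was vetoed: re-detect from a candidate
            # cluster.  A cluster consistent with the (unvalidated) internal
            # track wins over a more confident far one — a spurious veto must
            # not teleport the track
            clusters = self._cluster(candidates)
            best = None
            if internal is not None:
                near = [
                    cl for cl in clusters if self._mean_box(cl).overlap(internal) > 0.5
                ]
                if near:
                    best = max(near, key=lambda cl: sum(c.conf for c in cl) / len(cl))
            if best is None:
                best = max(clusters, key=lambda cl: sum(c.conf for c in cl) / len(cl))
            conf = sum(c.conf for c in best) / len(best)
            if len(best) >= 2 or conf >= cfg.reinit_min_conf:
                box = self._mean_box(best)
                # gate re-initialization on conservative similarity: the
                # earliest positive exemplars are the cleanest views of the
                # probe, so a stable instrument passes while drifted
                # background look-alikes do not
                patch = extract_patch(gray, box, cfg.patch_size)
                if self.model.conservative_similarity(patch) > cfg.nn_threshold:
                    final = box
                    source = "detector"

        if final is not None:
            final = self._clip_box(final, gray.shape)
            if final is None:
                source = None

        if learn and final is not None:
            self._pn_update(gray, final, cache, candidates)
            adaptive_posterior_update(self.ensemble, self.n_positive, self.n_total)

        self.box = final if final is not None else internal
        self.prev_gray = gray
        return StepResult(final, source, tracker_valid, len(candidates))

    # -------------------------------------------------------------- learning
    def _pn_update(
        self,
        gray: np.ndarray,
        final_box: BoundingBox,
        cache,
        candidates: list[_Candidate],
    ) -> tuple[int, int]:
        """P-expert: overlapping windows the ensemble missed become positives;
        N-expert: distant windows it fired on become negatives.  Returns the
        (n_positive_added, n_negative_added) sample counts."""
        cfg = self.config
        added_pos = 0
        added_neg = 0
        # the accepted box's own codes count as a positive sample if the
        # ensemble scored them at or below threshold (a P-expert correction)
        blur = gaussian_filter(gray, 1.0)
        own = self._box_codes(blur, final_box)
        if float(self.ensemble.posterior_sums(own[None])[0]) <= self.ensemble.threshold:
            self.ensemble.update(own, positive=True)
            added_pos += 1
        for scale, sel, codes, sums in cache:
            if sel.size == 0:
                continue
            iou = _iou_arrays(
                scale.x0[sel], scale.y0[sel], scale.w, scale.h, final_box
            )
            missed = np.nonzero((iou > 0.6) & (sums <= self.ensemble.threshold))[0]
            if missed.size:
                order = missed[np.argsort(-iou[missed], kind="stable")]
                take = order[: cfg.max_p_samples]
                self.ensemble.update(codes[take], positive=True)
                added_pos += take.size
            false_pos = np.nonzero((iou < 0.2) & (sums > self.ensemble.threshold))[0]
            if false_pos.size:
                order = false_pos[np.argsort(-sums[false_pos], kind="stable")]
                take = order[: cfg.max_n_samples]
                self.ensemble.update(codes[take], positive=False)
                added_neg += take.size

        patch = extract_patch(gray, final_box, cfg.patch_size)
        if self.model.relative_similarity(patch) < 0.65:
            self.model.add_positive(patch)
        n_hard = 0
        for c in candidates:
            if c.box.overlap(final_box) < 0.2 and n_hard < 3:
                self.model.add_negative(extract_patch(gray, c.box, cfg.patch_size))
                n_hard += 1

        self.n_positive += added_pos
        self.n_total += added_pos + added_neg
        return added_pos, added_neg


def track_video(
    frames, init_box: BoundingBox, config: TrackerConfig | None = None
) -> TrackResult:
    """Run the full TLD loop over a frame sequence.

    Frame 1 carries the manual probe annotation (``init_box``); the trajectory
    entry for it is the annotation itself.
    """
    frames = list(frames)
    if not frames:
        raise ValueError("no frames")
    tracker = TldTracker(frames[0], init_box, config)
    trajectory: list[BoundingBox | None] = [init_box]
    steps: list[StepResult] = [StepResult(init_box, "tracker", True, 0)]
    for frame in frames[1:]:
        res = tracker.step(frame)
        trajectory.append(res.box)
        steps.append(res)
    return TrackResult(trajectory, steps)
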