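# Methods

This note documents the models, the synthetic study conditions, the numerical
choices, and the limitations of the `vebird` toolkit: eye (iris) detection,
surgical-probe tracking, and lens-nuclear-hardness grading for
phacoemulsification cataract surgery video.

## 1. Eye detection: improved randomized Hough transform

**Model.** The iris contour is modeled as a conic in the reduced form
`x² + 2bxy + cy² + 2dx + 2ey + f = 0` (the general conic normalized by its
x² coefficient, valid for every ellipse). Five distinct edge points determine
the parameter vector `(b, c, d, e, f)` through a 5×5 linear system; the
configuration is an ellipse iff `b² − c < 0`. Circles are the 3-parameter
specialization `(cx, cy, r)` determined by point triples.

**Algorithm.** Randomized Hough transform: sample minimal point groups from
the edge image, solve each for its shape parameters, and vote each parameter
into its own 1-D accumulator (the 5-D/3-D joint space decomposes into
per-dimension histograms when the image contains a single dominant contour).
Two modifications matter in noisy surgical frames:

* *Distance-constrained sampling* — all pairwise distances inside a sampled
  group must reach `min_pair_distance` (default 5% of the point-cloud
  diagonal; 0 disables). Groups mixing a contour point with an adjacent
  clutter point produce wildly wrong conics; excluding tight groups removes
  most invalid votes and also improves the conditioning of the 5-point
  system on quantized coordinates.
* *Circle-then-ellipse cascade* — the 3-parameter circle detector runs
  first; the 5-parameter ellipse detector runs only when it fails. Circle
  failure is declared when any accumulator peak is below `vote_threshold`
  (default 15 groups) or when fewer than half of the edge points lie within
  2 px of the winning circle; the inlier criterion is what rejects
  foreshortened (elliptical) irises and defers them to the ellipse stage.

**Numerical choices.**

* 5-point systems are solved in centered/RMS-scaled coordinates and the
  conic is mapped back through the similarity transform; residuals are
  normalized by the coefficient and monomial norms, so "passes through the
  points" means a scale-free residual below 1e-6.
* Accumulators use 256 bins spanning the 0.5–99.5 percentile band of the
  votes (raw min/max would let a single wild conic stretch the bins
  arbitrarily). The returned peak parameter is the median of the votes in
  the peak bin and its two neighbours, not the raw bin center, because the
  bin width can exceed the parameter accuracy the later stages need.
* The assembled peak hypothesis is refined by two rounds of inlier selection
  (first-order point-to-conic distance ≤ 2 px) and an algebraic
  least-squares conic fit (SVD null vector, normalized coordinates). Bin
  quantization alone cannot reach pixel-level tolerances.
* Edge preprocessing: luminance → Canny (σ = 1.4, scikit-image percentile
  thresholds) → component denoising. Denoising dilates the edge mask by
  3 px, labels the dilated mask, and keeps components holding at least 20
  original edge pixels: dotted synthetic contours survive (dilation bridges
  small gaps) while scattered noise responses are removed. An input that is
  already a sparse binary mask is taken as an edge map directly.
* A detection is *correct* when it encircles the iris and is encircled by
  the limbus, both checked on 360 boundary points with a containment slack
  of 0.02 in normalized radius (~1 px at iris scale) absorbing the pixel
  quantization of the fixtures; strict checking is available.

## 2. Probe tracking: adaptive tracking-learning-detection

**Components.** Median Flow tracker (10×10 point grid in the box, pyramidal
Lucas-Kanade forward and backward, discard points with above-median
forward-backward error or below-median 5×5 patch correlation, move the box
by the median displacement and rescale by the median pairwise-distance
ratio); a scanning-window detector (variance filter → fern ensemble →
nearest-neighbour confirmation) over a 1.2ˣ scale grid with 10% stride; and
P-N learning (windows overlapping a reliable output that the ensemble called
negative become positive samples, distant windows it called positive become
negatives; the nearest-neighbour model is updated analogously).

The pyramidal Lucas-Kanade tracker is implemented in-package (2 levels,
9×9 windows, 10 Gauss-Newton iterations, bilinear sampling), vectorized
across points.

**Output-versus-track separation.** The frame output is the median-flow box
only when the detection cascade validates it (fern posterior sum strictly
above `0.5 × n_ferns` *and* nearest-neighbour relative similarity above
0.5); otherwise the frame is reported **absent** while the internal track
persists (and coasts in place if frame-to-frame tracking fails). This
mirrors how a tracking-by-detection system loses a slender instrument: the
annotation rectangle contains background, the background changes, the
ensemble mislabels the patch, and the output disappears even though the
probe is still in the box. Re-detection from candidate clusters restores the
output; a cluster consistent with the internal track is preferred over a
more confident far one, and overriding a *validated* track requires an
unambiguous far cluster with at least two windows and a clear confidence
margin (+0.10), because teleporting a good track is the costliest mistake
the integrator can make.

**Adaptive posterior rule.** Each fern answers an unseen code with 0 — after
a background change most codes are unseen, the ensemble sum collapses, and
the output goes absent for long stretches. A randomly chosen fifth of the
ferns (⌈n/5⌉, drawn once at initialization) instead answer unseen codes
with a running prior: 0.5 before any training data, afterwards the ratio of
positive to total P-N training samples, refreshed every learning step. Codes
with observed counts always keep their evidence-based posterior, and with an
empty adaptive subset the tracker *is* the classical baseline, bit for bit
(the subset draw consumes the same random numbers either way). The rule
trades a small false-positive risk (during a full occlusion the prior can
briefly validate a background box) for robustness against the
absence-starvation spiral, in which no output means no learning, which means
ever fewer seen codes.

**Defaults.** 10 ferns × 8 comparisons (256 leaves; at the 160×120 desk
scale of the fixtures, 13-comparison codes almost never recur, which starves
the posterior tables — larger scenes with longer videos can raise
`n_pairs`), 15×15 normalized patches, NN confirmation threshold 0.55
(annotation boxes are roughly half background here, which compresses
similarity contrasts; tight boxes warrant 0.6), validation threshold 0.5,
learning gate on conservative similarity 0.58 (a deliberately strict gate:
one wrongly validated frame that slips into the positive exemplars keeps
re-validating the wrong location, so learning waits for high-confidence
frames), forward-backward failure threshold 10 px. Initialization trains on 40 jittered copies of the
annotated box (±1.5 px, ±5% scale) and 100 distant windows.

## 3. Cataract grading: color features and a cascaded SVM

**Tissue ROI.** The patch ahead of the probe tip: the tip is the midpoint of
the probe-box edge nearest the eye center, and a square ROI (default 32 px)
is centered half a side beyond the tip along the tip-to-center direction —
the material the probe is about to emulsify. If the eye center lies inside
the probe box the direction degenerates and the ROI is placed above the box
(toward −y), a fixed tie-break. The ROI is clipped to the frame, must keep
its center inside the eye ellipse, and is resampled to 32×32.

**Features.** `f(I)` concatenates the 1024 raw pixel colors (row-major) and
the 64 mean colors of the 8×8 grid of 4×4-pixel cells (row-major), channels
scaled to [0, 1]: 3·(1024 + 64) = 3264 dimensions for every patch. The cell
means are redundant given the raw pixels but inexpensive noise-robust
aggregates; `means_only=True` keeps just the 192 cell-mean entries.

**Cascade.** Stage 1 (RBF-SVM) decides normal vs cataract; grade 0 returns
immediately and stage 2 — an RBF-SVM over grades 1–5 with one-vs-one voting
— is provably never consulted (the call counter is part of the public
surface so the short circuit is testable). Hyperparameters come from
grid-search cross-validation: C ∈ {2⁻², 2², 2⁶, 2¹⁰}, γ ∈ {2⁻¹⁰, 2⁻⁶, 2⁻²,
2²}, stratified 5-fold. The search runs on a stratified subsample of at most
600 patches — grid-search cost grows with the square of the kernel matrix
and the fixture classes separate at any reasonable hyperparameters — and the
selected parameters are refit on the full training set. Grid, folds and cap
are configurable. The KNN baseline uses 5 neighbours, Euclidean distance
over the same features, majority vote, ties broken by smallest mean
neighbour distance.

## 4. Synthetic study conditions

No surgical video can ship with this package, so every stage is exercised on
seeded generators whose outputs carry the statistical structure the
algorithms assume. All generators are pure functions of their spec (seed
included) and always emit ground truth.

* **Edge images** (detector): exactly `n` distinct pixels sampled on the
  iris ellipse plus `⌈f/(1−f)·n⌉` uniformly scattered noise points, so the
  true-point fraction is `1−f`. Defaults: 256×256, 200 contour points,
  f = 0.3. Noise is uniform over the image, not clustered.
* **Probe videos** (tracker): a rigid textured bar occupying the central 45%
  of its annotation box (a rectangle annotation of a slender instrument
  contains background), moving 1.5–2 px/frame over a background whose
  appearance rotates through a two-field blend `cos φ·F₁ + sin φ·F₂`
  (Gaussian-filtered noise fields, smoothness σ = 5 px) with φ advancing
  0.08 rad/frame — an everywhere-small appearance change with no coherent
  motion. Occlusion frames omit the probe and mark ground truth absent.
  Defaults: 160×120, 40×24 box, 200 frames, occlusion at frames 90–99.
* **Tissue patches** (grader): 32×32, per-grade mean RGB + i.i.d. Gaussian
  channel noise (σ = 10 on the 8-bit scale), clipped. Grade colors verbalize
  the Emery-Little descriptions: normal (200,160,160), I transparent
  (235,235,235), II yellow-white (230,220,140), III dark yellow
  (190,150,40), IV brown/amber (150,100,40), V dark brown (70,50,30).
* **Surgery videos** (pipeline): sclera-gray frame, grade-colored iris disc
  with σ = 10 pixel noise, a dark limbal ring just *outside* the iris
  boundary (both of the ring's edge contours then lie inside the iris–limbus
  acceptance band, so locking onto either is correct), and an orbiting
  probe bar. Defaults: 240×180, circular iris r = 62, limbus 1.3×, 100
  frames.

**What the fixtures do not contain** — specular highlights, irrigation
fluid, instrument shadows, pupil texture, illumination changes, deformable
tissue, annotation noise. Passing on these fixtures demonstrates the
algorithms' contracts (noise robustness of the voting scheme, the absence /
re-detection dynamics, color separability), not clinical performance;
frame sizes and rates of real microscope video are unknowable from the
fixtures and all sizes here are configurable.

## 5. Evaluation

Overlap rate `OR = area(ROI_T ∩ ROI_G) / min(area(ROI_T), area(ROI_G))` — a
deliberately lenient denominator, since the probe's true spatial extent is
ill-defined; a frame is correct iff `OR > 0.5` (strict), and precision is
the exact ratio `#correct/#frames` (integer arithmetic; no floating drift).
OR is undefined for absent frames: absent/absent counts correct,
present/absent mismatches incorrect (configurable). The pipeline recomputes
eye detection every 10th frame and holds the last result in between —
linear interpolation between scheduled detections would let a frame's output
depend on a *later* frame, which the per-frame composition forbids;
`eye_every=1` restores per-frame detection.

## 6. Known limitations

* The adaptive prior can validate a background box for a few frames during
  a full occlusion (reported present while ground truth is absent); the
  classical ensemble, which fails harder elsewhere, vetoes those frames.
  The improvement claim is therefore directional and holds in the mean over
  videos, not uniformly per frame.
* Median-flow scale estimation can shrink the box toward the textured bar
  over hundreds of frames; the min-area overlap metric is insensitive to
  this, but consumers needing tight boxes should re-detect periodically.
* On normal-tissue (grade 0) surgery fixtures the ROI occasionally clips the
  bright probe tip, shifting a few frames' grades; colored-grade fixtures
  are unaffected.
* `extract_tissue_roi` assumes one probe and a roughly convex eye region;
  multi-instrument scenes are out of scope.
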