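# Methods

This note documents the models and procedures implemented in `temposeg`,
the parameter choices that matter, what the synthetic data does and does
not emulate, and the numerical conventions — the background a maintainer
or reviewer needs to interpret the test suite and `scripts/acceptance.py`.

## Data model and normalization

A movie is a T×H×W stack; everything downstream operates on per-pixel
time series. Each pixel is min–max normalized **over time, per pixel**
(not over the whole movie): non-constant pixels map exactly onto [0, 1],
constant pixels are filled with 0 and flagged. This normalization is the
statistical engine of the method: background pixels containing only
low-amplitude noise are stretched to full range, while tissue pixels are
dominated by their action-potential (AP) waveform. Tissue and background
therefore remain separable in window space even when every frame in the
window is diastolic, provided the normalization window includes a beat.

Frame indices are 1-based in all public APIs (frame 1 is the first
frame); pixels are linearized row-major, so row p of a feature matrix is
pixel (p // W, p % W). A window (i, n) covers frames i … i+n−1 and
requires i+n−1 ≤ T.

Two normalization scopes exist:

* **movie** (default): min/max over the full record; windows inherit
  them. Right for static scenes — quiescent tissue stays anchored near 0.
* **window**: min/max recomputed inside each window. Required for moving
  objects: under full-record normalization, a pixel the object vacates
  keeps the record-wide dynamic range, so its noise-only stretch
  normalizes to a tight near-constant trace. Those vacated pixels form a
  compact third blob that two-cluster k-means *optimally* isolates (we
  verified the truth-seeded partition has higher within-cluster sum of
  squares), destroying the object/background split. `tracking_segment`
  therefore defaults to per-window normalization.

## Discounted k-means and stubborn-point harvest

Assignment rule: with centroids c₁, c₂ and Euclidean distances D₁, D₂, a
point joins the discounted cluster (say 1) iff γ·D₁ ≤ D₂, γ ∈ (0,1].
Ties go to the discounted cluster, which keeps the rival's stubborn set
conservative. γ is applied to the *unsquared* distance. Only the range
(0,1] is accepted; discounting the other side by γ is equivalent to
multiplying this side by 1/γ, so a parameter above 1 is never needed —
`discounted_index` chooses the direction instead.

Fitting is Lloyd iteration with the discounted assignment: k-means++
seeding from the given seed, 5 restarts keeping the lowest undiscounted
within-cluster sum of squares, convergence when assignments stop changing
or the largest centroid shift drops below `tol` (1e-6), `max_iter` 300.
An emptied cluster is reseeded from the point farthest from the surviving
centroid (with a warning). Identical seed, data and parameters give a
bit-identical model. With γ = 1 the fit is plain Lloyd k-means and (under
shared initialization) converges to the same partition as scikit-learn's
implementation; that equivalence is a standing oracle test.

**Harvest.** A plain γ=1 fit establishes the centroids and their semantic
identity. Two discounted fits are then started *from those centroids*
(not from fresh seedings — this keeps cluster identity stable so the
discounted side can be chosen programmatically): discounting the
background centroid leaves the stubborn tissue pixels, discounting the
tissue centroid leaves the stubborn background pixels. Pixels claimed by
both runs are contradictory and dropped from both classes. Default
γ = 0.8 for both sides.

**Auto-tuned γ.** A fixed discount can over-discount when the clusters
are weakly separated (short windows): in that regime γ = 0.8 can shrink
one class to a handful of pixels or collapse it entirely. When a target
training-set size is given, γ is instead found by bisection so each
confident set retains a target fraction (default one half) of its plain
cluster. `tracking_segment` uses this mode (`gammas="auto"`).

**Identity drift.** Aggressive discounting can drag the discounted
centroid into the rival cloud, silently swapping which cluster means
"tissue". Every discounted fit is therefore validated against the
expected object identity; a drifted fit counts as collapsed during
auto-tuning and raises otherwise.

**Object-cluster identification.** The tissue cluster is recognized by
its centroid's *autocorrelation-gated amplitude*:
`std(centroid) × max(lag-1 autocorrelation, 0)`. Only tissue pixels share
a waveform, so averaging preserves the tissue centroid's amplitude, while
a background centroid — whether i.i.d. noise or per-pixel baseline
wander — averages toward a flat trace; the autocorrelation gate rejects
the high-variance *white* centroid that appears when a cluster is
reseeded from a single noisy pixel. Scores closer than 1e-6 raise an
ambiguity error; an explicit override is available everywhere. Simpler
scores were rejected for cause: plain lag-1 autocorrelation cannot
separate a waveform from averaged baseline wander (both are smooth), and
the autocorrelation of the differenced centroid is destroyed by a single
sharp upstroke inside the window.

## Classifiers

Features are already in [0, 1] per pixel, so no further standardization
is applied (a flag exists). Both classifiers reduce, after fitting, to a
plain linear rule w·x + b stored in a backend-free `LinearClassifier`
(JSON-serializable).

* **Logistic regression**: scikit-learn's cross-entropy fit (lbfgs),
  weak L2 regularization by default (C = 1000) — enough for numerical
  stability in very high dimensions while staying an essentially
  unregularized maximum-likelihood fit. Threshold: probability 0.5,
  i.e. w·x + b ≥ 0.
* **Linear SVM**: soft-margin, true hinge loss (LinearSVC dual solver,
  pinned random_state, C = 1.0 default). Hinge rather than squared hinge:
  the squared penalty grows quadratically on mislabeled points and
  measurably destabilizes the fit under label noise. Threshold: decision
  value 0.

Stratified train/validation splitting at a ratio (default 8:1) puts
`round(class_size × val/(train+val))` rows of each class into validation,
deterministically under the split seed. Solver non-convergence emits a
warning carrying the diagnostics (m, n, iterations); the hyperparameter
`raise_on_nonconvergence` upgrades it to an error. A hard default error
was rejected because the interesting high-dimension regime is exactly
where the solver exhausts its budget.

## Mask median filter

For each pixel (value v), the 8 surrounding pixels are counted
(`neighborhood` may be any odd size ≥ 3; out-of-frame neighbors count as
value 0, since background surrounds the frame); the pixel keeps v iff
strictly more than `threshold` (default 3) neighbors share it. All counts
come from the input mask of each pass (synchronous update), so the result
is independent of scan order. `remove_heart` / `remove_background` gate
whether 1- and 0-valued pixels may flip; with both off the filter is the
identity. Default one pass, applied after classification.

## Polygon labeling path

The manual alternative to the harvest: polygons (row/col vertices, JSON
on disk) label every pixel whose center lies strictly inside; features
are the pixel's full T-frame normalized series. Simple (non-self-
intersecting) polygons only; overlapping polygons with conflicting labels
are an error listing the pixels. Point-in-polygon tests use shapely.

## Synthetic movies

The generator emulates the structure the method assumes, with ground
truth attached:

* **Object signal**: baseline + amplitude × AP(t − delay) + N(0, σ_obj).
  The AP pulse is a linear upstroke (default 5 frames), then an
  exponential plateau decay with time constant (APD − upstroke)/3,
  then baseline until the next cycle. Defaults: 250-frame cycle at
  1 kHz (4 Hz pacing), APD 150 frames, amplitude 0.5, baseline 0.2,
  σ = 0.02 — a clean, strongly modulated recording. An optional
  conduction delay, linear in distance from the pacing corner, staggers
  the upstroke across the tissue.
* **Background**: baseline + N(0, σ_bg), i.i.d. per pixel and frame,
  optionally plus per-pixel baseline *wander* (a Gaussian random walk,
  default off). Wander matters: pure i.i.d. noise, once min–max
  normalized, centres every background pixel at 0.5 — an artefact that
  makes even very short windows trivially separable and hides the real
  difficulty of small-n clustering. Real fluorescence backgrounds drift
  with illumination and bleaching.
* **Geometry/motion**: disk, ellipse or polygon object, rasterized by
  pixel-center inclusion per frame; rigid rotation (deg/frame) or
  isotropic shrinking (scale/frame). Truth masks follow the motion
  schedule exactly.

Deliberately *not* modeled: ionic-model electrophysiology, optics/PSF
blur, photon (Poisson) noise, spatially correlated noise, contraction
deformation beyond rigid motion. Passing tests therefore demonstrate the
algorithmic properties of the pipeline under the method's own
assumptions, not performance on any particular instrument's recordings.

## Canonical experiments (`temposeg.experiments`)

All headline numbers come from fixed study conditions at the method's
design scale, 100×100 px × 1,024 frames:

* **Static recovery** (default movie, n = 256, γ = 0.8): combined-SVM
  accuracy vs truth and pseudo-label precision, seeds 0–4.
* **Window-size trend** (σ = 0.05, wander 0.002, first upstroke at frame
  28 so the n = 32 window is nearly diastolic — the regime in which
  short-window k-means genuinely struggles while the few in-window
  upstroke frames still anchor cluster identity): plain k-means vs
  combined accuracy at n ∈ {32, 128, 256, 512, 1024} and the population
  STD of the heart ratio across n.
* **High-dimension degradation**: a sparse-signal dataset (32 informative
  of n dims, class separation 0.3, σ 0.15, 15 % of training labels
  flipped, 500/class train, 1000/class validation). Logistic regression
  runs at the package's weak default regularization; the SVM's C is
  chosen by 5-fold cross-validation on the training set, as a
  practitioner would. Going from 128 to 1024 dimensions the weakly
  regularized logistic fit absorbs the label noise through the nuisance
  dimensions (validation accuracy drops by 0.05–0.11 across seeds) while
  the margin-regularized SVM moves by < 0.01.
* **Tracking** (n = 32, per-window re-harvest, auto-γ, per-window
  normalization): ellipse rotating 0.35°/frame, disk shrinking
  0.9996/frame (to ≈ 44 % of its area), 100-frame cycle with APD equal to
  the cycle (continuous repolarization, as in fast-paced calcium
  recordings — a 32-frame window of flat diastole carries no class
  information), σ = 0.01. Windows every 32 frames (rotation) or 64
  (shrinking, where the readout is the monotone area trend and each
  sample must shed clearly more area than per-mask jitter).

## Known limitations

* Two classes only (one object); k > 2 is out of scope.
* Small objects: once the object falls below roughly 7 % of the frame,
  two-cluster k-means prefers splitting the large background cloud over
  isolating the object, and the harvest fails with it. The shrink
  experiment keeps the object above that envelope.
* Short windows need in-window signal: under per-window normalization a
  fully diastolic window is unclassifiable in principle.
* Cluster identification assumes the background centroid averages flat;
  a *globally coherent* background artifact (lamp flicker shared by all
  pixels) would survive averaging and could defeat it — use the
  override.
* The logistic-regression collapse is reproduced as a trend under weak
  regularization and label noise; a strongly regularized logistic fit
  does not show it.
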