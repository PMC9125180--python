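# Methods

This note documents the models and procedures implemented in `pawtrack`,
the defaults and why they were chosen, what the synthetic generators do and
do not emulate, and the numerical conventions that make results
bit-reproducible.

## Tracking tables and conditioning

A tracking table holds per-frame x/y (and optionally an estimator
likelihood in [0, 1]) for each named body part, a frame rate, and a unit
tag (`pixel` or `cm`). Coordinates use the image convention — origin
top-left, y increasing downward — because that is what pose estimators
emit; every angle and map in the package states this convention. Frame
indices are 0-based and contiguous; time windows are half-open
`[start_s, end_s)` and select frames `[floor(start·fps), floor(end·fps))`.

**Likelihood cutoff.** Frames with likelihood below the cutoff (0.9 by
default, the conventional operating point for DeepLabCut-style
likelihoods) are *repaired*, not dropped: x and y are linearly interpolated
between the nearest confident frames, with nearest-valid fill at the
recording boundaries. Dropping frames would contract the time axis and
corrupt speed estimates; forward-filling would create spurious zero-speed
runs. Interpolation keeps the kinematic series continuous and is
idempotent at a fixed cutoff (anchors are untouched). The per-part count
of conditioned frames is always returned so the repair is visible. A body
part with *no* confident frame is an error naming the part.

**Calibration** is a single isotropic cm/px scale from one known physical
reference (e.g. a 59 cm arena wall measured in pixels). No homography or
lens correction: for top-down open-field video the projective distortion
is small relative to pose jitter, and a one-length calibration is what
users can actually supply.

## Kinematics

Backward first differences: `d_i = ‖p_i − p_{i−1}‖`, `speed_i = d_i·fps`,
`accel_i = (speed_i − speed_{i−1})·fps`, with frame 0 of both series set
to 0. Mean/max speed summarise frames 1..n−1. No smoothing is applied by
default — raw differences are the transparent definition — but a centred
moving-average smoother (odd window) is available because pose jitter
inflates instantaneous speed; enabling it is an explicit, logged choice.

Orientation is `atan2(Δy, Δx)` from a reference part to a tip part,
mapped into (−π, π]; in image coordinates +π/2 points "down" on screen.
A helper converts to the mathematical (y-up) convention. Coincident
points yield NaN, never 0: a zero-length vector has no direction.

## Occupancy, areas, interactions

Occupancy is a plain 2-D histogram (numpy) over the data range or a given
extent; edges are returned with counts so any rendering is reproducible,
and multiple animals can be pooled. Σcounts always equals the number of
valid frames.

Areas are named rectangles (top-left origin, width, height) or circles
(center, radius). Membership: rectangles half-open (`origin ≤ p <
origin+size`) so adjacent rectangles tile without double-counting; circles
closed. An interaction event is a maximal run of consecutive frames with
the chosen body part inside an area; events are reported chronologically
(ties by label) with inclusive frame bounds and `duration =
(end−start+1)/fps`. No minimum-duration debounce by default (an optional
`min_frames` exists); interaction is point-in-region of one body part, not
a proximity threshold. A compatibility importer accepts the legacy
8-element positional area descriptor, interpreting its last four entries
as x, y, width, height — heuristic, clearly marked, since the first four
entries' semantics are not recoverable.

## Behavior classification

**Features.** All unordered pairwise distances between the selected body
parts (k parts → k(k−1)/2 columns, lexicographic order). Distances are
invariant to translation and rotation of the animal, so posture — not
position — drives everything downstream. Features are raw distances by
default; an optional z-scoring flag exists because Ward on unscaled
distances weights long body segments more, which may or may not be
desirable.

**Clustering.** Ward-linkage agglomerative clustering (scipy) on Euclidean
distances between feature rows. The merge height is
`sqrt(2·|A||B|/(|A|+|B|))·‖c_A − c_B‖` — the square root of twice the
increase in within-cluster sum of squares. Cutting all merges above a
user-chosen threshold yields the behavior clusters; the threshold is in
merge-height units *of the feature space*, so the same number means a
different granularity on cm features than on pixel features (units are
echoed in the output). Labels are re-indexed by decreasing cluster size,
ties broken by first-occurring frame, so output is deterministic. Frames
are classified independently; an optional temporal mode filter (default
off) can suppress single-frame flicker. `gap_threshold` returns the
midpoint of the merge-height gap yielding a requested cluster count —
convenient when the count is known, as for synthetic scenes.

**Embedding.** t-SNE (scikit-learn) initialised from the first two
principal components scaled so PC1 has standard deviation 1e-4 — small
enough for early exaggeration to organise the map while keeping the PCA
global arrangement. Learning rate `n/12` exactly; perplexity `n/100`
clamped below at 5 (the formula degenerates for small n: perplexity must
stay well above 1, and n/100-style heuristics are calibrated on large
datasets — the clamp engages below n = 500). With fixed input, config and
seed the embedding is bit-reproducible. At least 30 frames are required so
the perplexity constraint `perplexity < (n−1)/3` holds.

**Embedding quality.** KNN: mean over points of the shared fraction of
k-nearest-neighbour sets (k_local, default 10) between feature space and
embedding. KNC: mean over classes of the preserved fraction among each
class's k nearest class centroids (k_class, default `min(4, C−1)`);
classes are the agglomerative clusters themselves, since no external
labels exist in an unsupervised pipeline. CPD: Spearman correlation of
pairwise distances over a seeded subsample (default 1000 points). For a
random embedding the expected KNN is k/(n−1) and CPD ≈ 0 — the null
levels the tests calibrate against.

**Inspection support.** Per-cluster representative frames are chosen
nearest the cluster medoid (the member minimising summed feature-space
distance to its cluster, O(m²) per cluster — fine at session scale). The
package emits frame *indices*; extracting the actual video frames is the
experimenter's step, as is naming clusters (rearing, grooming, ...) —
semantic naming requires a human.

## Neural coupling

Alignment is an explicit contract: video frame 0 ↔ signal time `t0_s`,
supplied by the user; no sync-pulse detection. Epoch sample indexing is
half-open with round-to-nearest boundaries —
`[round((start−t0)·f), round((end−t0)·f))` — so epochs cut at a partition
of the recording concatenate back to it sample-for-sample. Event inputs
may be plain second intervals, interaction events (with an fps to convert
frames), or behavior intervals (which carry their fps); epochs are keyed
chronologically and carry their source label.

Spatial activity maps bin a per-frame scalar (spike counts per frame, or a
continuous signal already averaged per frame — the reduction is the
caller's, stated explicitly) by body-part position: per-bin mean plus
visit counts, NaN where unvisited, so the visit-weighted mean recovers the
global mean exactly. Spectrogram rendering of epochs is a documented thin
wrapper over scipy's short-time transform, not a core operation.

## Synthetic data

The generators emulate the study conditions the analyses target: a
59×59 cm open-field arena sampled at 30 fps (the standard top-down
recording geometry), snout-led interaction, and four tracked body parts
for posture features.

* **Trajectories** — constant velocity, one circular revolution, or a
  bounded random walk (Gaussian steps, default 1 unit/frame, *reflected*
  at the walls so occupancy stays well defined). Duration fixes the frame
  count as `round(duration·fps)+1`, so n frames bound n−1 steps and the
  closed-form truths are exact: `speed·duration` for constant velocity,
  the chord sum `2r(n−1)sin(π/(n−1))` for the circle. Optional seeded
  dropouts (low likelihood + corrupted coordinates) exercise the
  conditioning path; the clean coordinates are kept as truth.
* **Behavior scenes** — per-cluster body-part geometry templates (default
  4 parts at ~10-unit body scale, 60 frames per cluster) defined in a
  body-centric frame and placed by a seeded random rotation + translation
  per frame, so absolute positions carry *no* cluster information — which
  is precisely what makes the rigid-motion invariance of the features a
  meaningful test. Coordinate noise is derived from a requested
  separation/noise ratio (minimum between-template feature distance over
  the within-cluster RMS feature spread `≈ sqrt(2m)·σ` for m features);
  the achieved ratio is reported as ground truth. Default ratio 10 —
  clearly distinct postures; recovery experiments use 5, the boundary of
  comfortable separability.
* **Event signals** — Gaussian noise (sd 1) plus a sinusoid (8 Hz, the
  rodent theta band) whose amplitude is multiplied by a gain (default 5)
  inside event windows; in-epoch variance is analytically `A²g²/2 + sd²`,
  which the tests check by simulation.

What the generators do **not** emulate: real pose-estimation error
structure (correlated jitter, identity swaps, occlusion runs), soft
cluster boundaries and transitional postures, non-stationary or 1/f-like
neural spectra, or multi-animal scenes. Passing tests therefore
demonstrate correctness of the computations and recoverability under the
stated geometry — not that any particular real dataset will yield clean
clusters.

## Numerical choices and problem sizes

CSV round-trips are bit-lossless (shortest-repr writing, round-trip float
parsing). Ward trees are verified against an O(n³) from-first-principles
agglomeration at n ≤ 40 (heights to 1e-8 relative; ties between equal
merge costs are measure-zero on continuous features and not otherwise
ordered). Event detection is verified against a per-frame membership +
run-length oracle on 200 randomized scenarios. Recovery experiments use
20 scenes of 2–6 clusters × 30 frames; embedding-quality calibration uses
n = 500 with k = 10; epoch conservation uses a 60 s, 1 kHz signal; the
place-field recovery uses 6000 frames on a 10×10 grid. These sizes give
fully converged checks (exact agreement, ARI 1.0, null-level scores) at a
few seconds of compute each; all are set in one place
(`scripts/acceptance.py` and the test suite) and scale linearly if larger
runs are wanted.

## Known limitations

Single-animal tables only (no identity tracking); rectangles/circles only
(no polygons); one isotropic calibration; no automatic video
synchronisation; threshold selection for the Ward cut is the user's
scientific decision (the dendrogram, histogram and gap helper support it,
they do not replace it); t-SNE quality scores are diagnostics of the 2-D
*map*, not of the clustering, which operates in the full feature space.
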