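# Methods

This note records the model underlying each stage of the pipeline, the
parameters that matter, the numerical choices, what the synthetic data do
and do not emulate, and the known limitations.

## Confidence gating

Tracking likelihoods from markerless pose estimators are empirically
bimodal: a high mode for well-seen points and a low mode for occlusions
and mistracks. We split the two modes per body part and per session with a
histogram elbow: 50 equal-width bins on [0, 1], scanned from the low end;
the threshold is the left edge of the first bin where the adjacent-bin
count difference turns positive after the descent out of the low mode.
Two robustness guards are applied: counts are smoothed with a 3-bin moving
average, and the upturn must occur in a genuine inter-mode valley (counts
below half the running maximum). Without the guards, Poisson noise in the
left tail of a *unimodal* high mode produces spurious elbows; with them, a
unimodal session falls back to the configured floor (0.1). Even so, on
unimodal sessions a spurious elbow deep in the tail occasionally survives
and forward-fills a frame or two (≈ 0.03% of frames in simulation) —
harmless downstream, since substitution only zeroes displacement.

Sub-threshold frames take the most recent high-confidence coordinate, so
their inter-frame displacement is exactly zero; leading low-confidence
frames are back-filled from the first good frame to avoid NaNs. Raw
likelihoods are preserved, which makes the operation idempotent. The
threshold is computed per part because occlusion statistics differ by part
(a snout occludes during rears; paws during postural shifts); a pooled
mode is available via `per_part=False`. A part with *no* high-confidence
frame raises an error naming the part — such a session is unusable for
that part rather than silently reconstructable.

## Features

For N parts, per frame transition t → t+1:

* `L` — Euclidean length of each of the N(N−1)/2 inter-part vectors
  (posture geometry, px);
* `Θ` — angular change of each inter-part vector between consecutive
  frames (degrees);
* `D` — Euclidean displacement of each part (movement, px).

This gives N² features (36 for N = 6). The first frame is dropped so all
streams share length T−1. Two deliberate numerical choices:

* **Θ is the unsigned magnitude `|atan2(cross, dot)|` by default**
  (equivalently, the arccos of the normalized dot product). Signed angular
  changes cancel when *summed* over 100 ms bins: for oscillatory limb
  movement the bin sum reduces to a sign ripple locked to the binning grid
  (bins alternately cover rising and falling half-strokes), which is an
  artifact of the grid, not a movement magnitude, and it split otherwise
  homogeneous behaviors into mirror-image sub-clusters. The signed variant
  (turning direction) remains available via `signed_angles=True`.
* **A zero-length pair vector yields Θ = 0** for that transition
  (coincident tracked points), never NaN.

Streams are smoothed with a centered boxcar of half-width
`round(0.03·fps)` frames (~60 ms total, truncated at stream edges) and
then aggregated into non-overlapping windows of `w = round(fps/10)` frames
(100 ms): `D` and `Θ` are summed, `L` averaged, and a trailing partial
window is dropped. Smoothing precedes binning because the 60 ms scale
would be sub-resolution after 100 ms aggregation. At fps < 17 the smoothing
half-width rounds to zero and streams pass through; fps < 10 is rejected.

## Group discovery

Feature columns are z-scored before both the PCA criterion and UMAP — px
and degrees are not commensurate, and distances (≈ body size) would
otherwise dominate displacements (≈ px/frame). The embedding
dimensionality is the smallest d whose top principal components of the
standardized matrix explain ≥ 70% of variance (d ≥ 2 enforced). UMAP runs
with `n_neighbors=60`, `min_dist=0.0`, Euclidean metric and a fixed
`random_state` — parameters chosen for density-based clustering rather
than visualization; with a fixed seed the embedding is reproducible but
its coordinates are still arbitrary, so all evaluation uses
permutation-invariant scores (adjusted Rand), never coordinates.

Clustering uses `sklearn.cluster.HDBSCAN` with `min_cluster_size`
defaulting to 1% of bins (fractions are converted with a ceiling) and
`min_samples` at its library default. `allow_single_cluster=True`: a
unimodal embedding is one behavior group, not all noise. Low-density bins
get label −1 and are excluded from classifier training (they purify the
training set). A noise fraction above 50% triggers a warning rather than
an error.

## Classifier

A random forest at scikit-learn defaults (100 trees, Gini, unlimited
depth, √P features per split, fixed seed) maps features to group labels.
The holdout is an unstratified random 20% of non-noise bins (stratification
available via `stratify=True`); the training report carries held-out
accuracy, the confusion matrix and per-class precision/recall. k-fold
cross-validation shuffles rows and reports per-fold accuracies with mean
and SEM. Prediction never emits the noise label and validates the feature
schema (names and order) before running.

Transfer across animal sizes is *not* guaranteed by raw pixel features
(`L` and `D` scale with the animal); in practice moderate size changes
(≤ 1.5×) transfer because frequency- and angle-borne structure is
size-invariant and the forest tolerates scaled split thresholds — on
synthetic data a model trained at scale 1.0 segments a 1.5× animal with
adjusted Rand ≈ 1.0 on unambiguous bins. Larger scale changes should be
handled by training on pooled animals.

## Frameshift

With `F = round(fps/10)`, features are binned at every offset
f ∈ {0…F−1}, predicted, and interleaved: `G[f + s·F] = g_f[s]`. Native
frames beyond the last complete bin of their offset stream inherit that
stream's final label, so `len(G) = T` exactly. Coherence upsamples the
offset-0 stream (the non-frameshifted prediction) by repeating each label
F times and reports per-group percent agreement with `G` over the frames
`G` assigns to that group, plus the median across groups.

Bouts are maximal constant-label runs of `G`, half-open in native frames.
Runs shorter than `min_bout_samples` (default 3, i.e. < 50 ms at 60 fps)
are excluded from the bout list — justified by the spurious-repeat bound
(1/K)^(n−1) — while the frame labels stay untouched. The two-view overlap
matrix reports `100·(P(tgt=j|ref=r) − P(tgt=j))/P(tgt=j)`: percent
enrichment of target group j within reference group r over j's baseline
prevalence, removing the bias toward frequent behaviors; negative entries
(depletion) are reported as-is, and a percentage-point difference variant
is one code path away if preferred.

## Kinematics

Limb speed is the per-frame displacement of one part under the same 60 ms
boxcar. Within a bout, speed peaks are detected with prominence
`0.5 × median bout speed` (configurable; the floor of 1e-12 keeps
`find_peaks` well-defined on flat speed, which yields zero strokes), and
the speed troughs before, between and after peaks delimit strokes. Per
stroke: peak and mean speed (the literature is ambiguous about which
"stroke speed" means, so both are reported), traveled path length, net
Euclidean displacement (≤ path by construction; numerically clipped), and
duration. Stride analysis applies the same trough-delimited definition to
locomotion-labelled bouts. Note the resolution limit: strokes are only
separable when the speed rhythm (2× the position rhythm) is slower than
the 60 ms smoothing window — at 60 fps that means stroke rates up to
roughly 4–5 Hz. Cohort comparisons are two-sample two-tailed
Kolmogorov–Smirnov tests with exported empirical CDFs; below 5 samples a
warning is raised but the result is still returned.

## Motion energy

A bout's motion-energy image is the mean |frame_{t+1} − frame_t| over at
most 600 ms of the bout, after translating frames so the pose centroid at
bout start sits at the image center. Registration is translation-only
(integer shift, zero fill); rotational alignment is a possible extension
but the translation step already removes the dominant arena-position
confound. For group validation, up to 20 bouts of 300–600 ms per group
enter an all-pairs MSE matrix (symmetric, zero diagonal); each row is
divided by its in-group mean (excluding the diagonal; a zero in-group mean
maps the row to 0), in-group and out-group normalized values are compared
by KS, and the identical images shuffled into random groups of the same
sizes provide the structureless control. Groups with fewer than two
eligible bouts are dropped with a notice.

## Neural alignment

Spike trains are aligned to behavior onsets: 10 ms bins over −1…2 s,
trial-averaged to rates, z-scored per neuron over the whole window
(before smoothing — the z rows have mean 0, SD 1 exactly), then smoothed
with a boxcar of semi-width 3 bins. Neurons can be rank-ordered by mean
activity in the 200 ms before onset for display. The resolution
comparison computes |z_high| − |z_low| per neuron and bin using the
smoothed traces, sums it across neurons (tuned neurons contribute
systematically, untuned ones cancel), reports mean ± SEM across neurons,
and flags bins with two-tailed one-sample t-tests at α = 0.01. An empty
spike train yields a zero row with a notice; a single neuron disables the
t-test with a warning.

The simulated neuron is an inhomogeneous Poisson process: constant
baseline with a step to an elevated rate for a fixed duration beginning a
fixed lead before each onset (defaults 5 → 15 Hz, 100 ms, 130 ms lead,
trials every 3 s). Alignment error of frame-quantized behavior onsets is
modelled as uniform jitter of ± half the inter-frame interval at the
stated fps — uniform, not Gaussian, because quantization error is bounded.
Aligning at 10 fps-jittered onsets convolves the 100 ms step with a 100 ms
box, flattening the plateau toward ~12.5 Hz and smearing rate mass into
the flanking 100 ms; 60 fps jitter leaves the plateau within sampling
error of the truth. This reproduces the biphasic
(better-before/worse-after) signature of high- vs low-resolution
alignment.

## Synthetic data: what it emulates, and what it does not

A session is a Markov chain over K movement motifs: per-frame switch
probability `1/(mean_dwell·fps)` (geometric dwell, default mean 0.45 s,
matching the duration scale of short behavior bouts), successor drawn from
the off-diagonal-renormalized transition matrix. Each motif specifies per
part a *linear* stroke oscillation — amplitude, frequency, phase, stroke
direction — around a posture offset, plus a whole-body drift velocity;
the body center reflects off the arena walls. The four default motifs
(6-part skeleton, px units): idle (0.5 px tremor at 10 Hz), locomote
(7 px limb strokes at a 10 Hz fast-trot rate, alternating gait, 40 px/s
drift), groom (9 px forepaw strokes at 7.5 Hz near the snout, compressed
fore-posture), rear (foreshortened skeleton — offsets' y compressed to
0.45 — with 3 px sway at 5 Hz).

Three generator design points matter and are deliberate:

* **Linear, not circular, strokes.** Circular part motion makes inter-part
  vectors genuinely rotate, flooding Θ with large phase-dependent sums;
  real steps and grooming strokes are back-and-forth.
* **Rhythms commensurate with the 10 Hz bin rate** (5, 7.5, 10 Hz — all
  realistic rodent stride/stroke/tremor rates). Each 100 ms bin then
  covers an integer number of half-periods, so binned statistics are
  stationary within a motif — the property real behavior has at this
  timescale. Incommensurate rates make bin statistics depend on oscillator
  phase at the bin boundary, which manufactures within-motif continua that
  are generator artifacts, not behavior.
* **Execution variability.** A per-bout uniform phase offset, a lognormal
  AR(1) "vigor" modulation of amplitudes (CV 0.15, correlation time
  0.3 s — strokes vary stroke to stroke), and 0.5 px white movement noise
  on every part. These model the fact that an animal is not a metronome,
  and they are distinct from the *tracking* noise (`jitter_sd`, default
  1 px Gaussian) and the likelihood model (high mode Beta(20, 1); dropout
  frames, default 2%, draw from Beta(1, 20)). With all execution terms
  zeroed, a single motif's trajectories are exactly periodic.

What passing tests on these data show: the pipeline separates behaviors
that differ in posture, movement magnitude and rhythm under realistic
tracking noise, recovers them across animals of different size, labels
every native frame consistently with the 10 fps signal, and recovers known
neural modulation. What they do not show: performance on real video
(photorealism, perspective, fur and limb self-occlusion are not modelled —
occlusion appears only as likelihood dropout), on behaviors defined by
subtler statistics than these motifs, or on multi-animal scenes. The
motion-energy analyses run on Gaussian-blob raster renderings of the pose
— a synthetic stand-in that preserves movement geometry, not appearance —
so the ME results are structural, not photometric.

## Evaluation conventions

Ground truth for a 100 ms bin is the majority motif among its frames
(`bin_labels`, with a purity score); bins straddling a motif switch have
no single true label, so headline recovery numbers quote both all-bin and
pure-bin adjusted Rand. Cluster-recovery tests use noiseless sessions with
2 s dwells so that straddle bins are rare and the test isolates cluster
structure from transition ambiguity. All stochastic steps take explicit
seeds; fixed seed implies bit-identical generator output and reproducible
embeddings, labels and forests.

## Problem sizes

The test suite runs sessions of 150–180 s at 30 fps (~1500–1800 bins) and
a 30 s session at 200 fps for the frameshift structure; the acceptance
script uses the full 10-minute 60 fps session (5999 bins) and 500-trial
spike simulations. These sizes put UMAP+HDBSCAN in the regime where
n_neighbors=60 is a small fraction of the data while keeping a full run in
about a minute.

## Known limitations

* Pixel-domain features: no spatial calibration, so cross-setup transfer
  assumes comparable px-per-cm and animal size (≤ ~1.5× differences).
* The elbow rule assumes a *bimodal* likelihood distribution; degenerate
  sessions fall back to a fixed floor of 0.1.
* Frameshift assumes behavior is piecewise constant at the 100 ms scale;
  events briefer than one bin are recoverable only through the offset
  ensemble, not within any single stream.
* Stroke segmentation cannot resolve rhythms faster than the 60 ms
  smoothing window allows (see Kinematics).
* HDBSCAN group counts depend on `min_cluster_size`; the 1% default is a
  starting point, deliberately exposed to the user.
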