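# poseseg

Unsupervised behavior segmentation, temporal super-resolution and kinematics
from 2D pose-estimation time series.

Modern markerless trackers (DeepLabCut and compatible tools) localize body
parts in every video frame, but positions are not behaviors: behaviors are
the conserved spatiotemporal *patterns* of those positions. `poseseg`
discovers those patterns without human labels and turns them into a
millisecond-scale ethogram plus per-limb kinematics — the quantities needed
to study grooming, locomotion and their disruption in models of OCD, pain
and movement disorders.

## The method

Given per-frame coordinates and tracking likelihoods for N body parts at
`fps` Hz:

1. **Confidence gating.** Tracking likelihoods are bimodal (confident vs.
   occluded/mistracked). Each part's session is split at the histogram
   elbow; sub-threshold frames inherit the last high-confidence position,
   so a low-confidence point contributes zero displacement.
2. **Spatiotemporal features.** Per frame transition: the length `L` of
   every inter-part vector (N(N−1)/2 distances), the angular change `Θ` of
   each such vector between consecutive frames, and each part's
   displacement `D` — N² features in total (36 for the 6-part rodent
   model). Features are smoothed over ~60 ms and aggregated into
   non-overlapping 100 ms bins (`D`, `Θ` summed; `L` averaged), trading
   tracker jitter for a robust 10 Hz movement signal.
3. **Group discovery.** Features are z-scored; the embedding
   dimensionality `d` is the smallest number of principal components
   explaining ≥ 70% of variance; UMAP (`n_neighbors=60`, `min_dist=0.0`,
   Euclidean) embeds the bins; HDBSCAN (user-tunable `min_cluster_size`,
   default 1% of bins) assigns groups, labelling low-density bins −1
   (noise).
4. **Classifier transfer.** A random forest (scikit-learn defaults) learns
   the map from the N²-dimensional features to the group labels on the
   non-noise bins. The forest — not the embedding — predicts new sessions
   and animals: fast, deterministic, and free of re-embedding drift.
5. **Frameshift super-resolution.** Predictions are made at 10 fps on each
   of the `F = fps/10` frame-offset versions of the session and
   interleaved (`G[f::F] = g_f`), labelling every native frame: a 200 fps
   video gets 20 passes, each advanced by one 5 ms frame. Bouts are
   maximal constant-label runs; runs under 3 samples (< 50 ms) are
   discarded as jitter, since an independent uniform label over K groups
   repeats three times with probability (1/K)² (< 1% for K = 11).
6. **Kinematics & validation.** Within bouts, limb-speed troughs delimit
   individual strokes/strides (peak detection with configurable
   prominence); cohorts are compared with two-tailed Kolmogorov–Smirnov
   tests. Group quality is validated by motion-energy image MSE (in-group
   vs out-group, with a shuffled control) and by peri-event time
   histograms of spike trains aligned to behavior onsets (10 ms bins,
   z-scored over −1…2 s, 3-bin boxcar).

A synthetic-data module generates ground-truth-labelled sessions
(Markov-switching movement motifs on a 6-part skeleton, Gaussian tracking
jitter, bimodal likelihood dropouts), raster video and Poisson spike
trains, so the entire pipeline is testable without any download.

## Worked example

```python
import poseseg as ps
from sklearn.metrics import adjusted_rand_score

session = ps.simulate_pose(duration=150.0, fps=30.0, seed=11)
clean, report = ps.substitute_low_confidence(session.pose)
features = ps.pose_to_features(clean)          # 1499 bins x 36 features
seg = ps.fit_segmentation(features, seed=11)
clf = ps.train(features, seg.cluster_labels, holdout=0.2, seed=11)
print(seg.n_components, seg.n_groups,
      clf.training_report["holdout_accuracy"])
```

Running this (it is `examples/01_segment_synthetic_session.py`) prints:

```
low-confidence points replaced per part: [2.18 1.96 1.93 1.73 1.58 1.82] %
feature matrix: 1499 bins x 36 features
embedding dimensionality d=3 (smallest d explaining >= 70% variance); 4 groups found, 100.0% of bins assigned
adjusted Rand vs generator ground truth (non-noise bins): 0.762
random forest agrees with cluster labels on 97.7% of held-out bins
```

The four synthetic motifs (idle, locomote, groom, rear) are recovered as
four groups; ~2% of points were low-confidence and forward-filled; the
adjusted Rand index of 0.76 against frame-level ground truth is limited
mostly by 100 ms bins that straddle motif switches (on unambiguous bins it
exceeds 0.95); and the forest reproduces the unsupervised grouping on
97.7% of held-out bins.

The other scripts in `examples/` walk through frameshift ethograms and
coherence (`02`), stroke kinematics with a lesion-style KS comparison
(`03`), motion-energy group validation (`04`) and neural alignment at
different temporal resolutions (`05`).

## Command line

Every stage is also a subcommand of the `poseseg` console script, with a
YAML config mirroring `RunConfig` and a `run_config.json` (config echo +
hash) written next to every artifact:

```bash
poseseg simulate --out sim/ --duration 600 --fps 60 --seed 3
poseseg train    --pose sim/pose.csv --fps 60 --out model/ --seed 3
poseseg predict  --pose sim/pose.csv --fps 60 \
                 --model model/classifier.joblib --out ethogram/
poseseg kinematics --pose sim/pose.csv --fps 60 \
                 --bouts ethogram/bouts.csv --part forepaw_r --out strokes.csv
```

Ethograms are exported as `(frame, label)` and
`(start_s, end_s, label, duration_ms)` CSV tables; bout intervals are
half-open `[start_frame, end_frame)` in native frames.

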