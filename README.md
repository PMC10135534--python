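# swarmflight

One-class classification and interpretation of 3D insect flight tracks in
mating swarms.

## What it does

Male mosquitoes aggregate at dusk into mating swarms, flying stereotyped,
quasi-circular loops above a ground marker; females and freshly formed
couples move through the same airspace with much shorter, more erratic
trajectories. `swarmflight` frames "is this track a swarming male?" as an
anomaly-detection problem:

1. **Windowing** — each 3D track (positions + timestamps) is cut into
   fixed-duration overlapping segments (default 1.6 s window, 0.8 s
   overlap); tracks shorter than twice the window are discarded.
2. **Feature extraction** — every segment is reduced to 237 descriptors:
   a nine-statistic summary (mean, median, standard deviation, quartiles,
   kurtosis, skewness, extrema count, zero-crossing count) of 25 kinematic
   series (speed, per-axis velocity/acceleration/jerk, radial
   acceleration/jerk, angle of flight, angular velocity/acceleration in
   three planes and 3D, the orthogonal persistence/turning/inclination
   velocity components, centroid distance), plus 12 scalar shape
   descriptors (straightness, convex-hull volume and area, planar
   curvature summaries, curvature-scale-space summaries, fractal
   dimension).
3. **Feature selection** — a Mann–Whitney U screen with Bonferroni
   correction (family α = 0.01) keeps features that separate male from
   non-male segments, then correlation pruning (|r| ≥ 0.85, transitive
   grouping) keeps one representative per redundant group.
4. **One-class detection** — a one-class SVM (ν = 0.20, RBF kernel) is
   trained on standardised male segments only; segments outside its
   boundary are called non-male.
5. **Track voting** — a track's label is the majority over its segments;
   an exact tie resolves to non-male.
6. **Evaluation** — leave-2-male-trials-out cross-validation (8 male
   trials → 28 folds) with a fold-averaged metric suite (balanced
   accuracy, per-class precision/recall/F1, ROC and PR AUC), percentile
   95% confidence intervals, and a pooled confusion matrix. A fixed
   subset of non-male trials is reserved for the feature screen and never
   tested, so no test data can leak into any fitted state.
7. **Attribution** — per-feature Shapley values of the detector's decision
   function, computed with a permutation-sampling estimator whose local
   accuracy (baseline + Σ attributions = decision) is exact per sampled
   draw.

A synthetic swarm generator (orbital male flight vs Ornstein–Uhlenbeck
perturbed erratic flight) provides labelled multi-trial datasets for
development, testing, and the end-to-end examples below.

## Worked example

Command line (the `swarmflight` console script):

```sh
# generate a synthetic labelled dataset (8 male + 9 non-male trials)
swarmflight simulate --seed 0 --out tracks.csv

# validate + summarise it, with trial-level QC flags
swarmflight ingest tracks.csv

# windowed feature matrix (one row per segment, 237 features + lineage)
swarmflight extract tracks.csv --window 1.6 --overlap 0.8 --out matrix.csv

# leave-2-trials-out evaluation
swarmflight evaluate tracks.csv --nu 0.2 --kernel rbf --out metrics.json

# or stage by stage: segment inventory, feature selection, detector
# training, and Shapley attribution of a saved model
swarmflight segment tracks.csv --out segments.csv
swarmflight select matrix.csv --out selection.json
swarmflight train matrix.csv --selection selection.json --out model.joblib
swarmflight explain model.joblib matrix.csv --out attributions.csv

# everything (QC, folds, metrics, attributions, manifest) in one run
swarmflight run-all --out runs/demo
```

As a library:

```python
from swarmflight.simulate import SimConfig, simulate
from swarmflight.evaluation import cross_validate
from swarmflight.detector import DetectorConfig

dataset = simulate(SimConfig(seed=0))
report, folds, matrix = cross_validate(dataset, config=DetectorConfig(nu=0.2))
print(report.mean["balanced_accuracy"], report.confusion)
```

Expected CSV schema for real data: long format with columns
`trial_id, track_id, label, t, x, y, z` (seconds and metres; labels in
`male`, `female`, `couple`, `focal_male`).

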