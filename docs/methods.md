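# Methods

This note records the model, its parameters, the numerical choices made in
the implementation, what the synthetic generator does and does not capture,
and known limitations. All defaults quoted here are the package defaults;
every one is overridable through the library API, the CLI, or a YAML run
configuration.

## 1. Data model

- **Track**: ordered 3D positions (metres) with strictly increasing
  timestamps (seconds), one tracked individual (or couple) each, carrying a
  class label in {`male`, `female`, `couple`, `focal_male`}.
- **Trial**: one recording session (one swarm); every track belongs to
  exactly one trial. Trials are the unit of cross-validation because
  tracks within a session share environment and swarm identity.
- **Expected outcomes**: `male` and `focal_male` tracks should be called
  male; `couple` and `female` tracks should be called non-male.

## 2. Windowing

Tracks are cut into equal-duration segments (default window 1.6 s, overlap
0.8 s; the hop is window − overlap). Windows are anchored at the track's
first timestamp; a trailing remainder shorter than the window is
discarded. At the nominal 25 Hz sampling rate a 1.6 s window holds 41
samples. Tracks shorter than twice the window are removed before
windowing (logged per class) so every retained track yields at least three
segments for voting.

## 3. Feature battery (237 features)

25 per-segment time series are each summarised by nine statistics
(mean, median, standard deviation with ddof = 1, first and third
quartiles, Fisher kurtosis and skewness in their biased population forms,
the count of local extrema, and the count of zero crossings), giving 225
features, plus 12 scalar descriptors.

Series: speed; signed radial acceleration d|v|/dt and its derivative
(radial jerk); per-axis velocity, acceleration and jerk (central
differences via `np.gradient`, edge order 2); angle of flight between
consecutive displacements (arccos of the clamped dot product, range
[0, π]); angular velocity and angular acceleration of the heading in the
XY, YZ, XZ projections and in 3D (the angle at step junction *j* is
divided by the junction time span (t[j+2] − t[j])/2); the orthogonal
velocity components persistence, turning and inclination (spherical
decomposition of consecutive displacements, satisfying
P² + T² + I² = v² identically); and distance to the segment centroid.

Scalars: straightness (path length / chord length, ≥ 1, NaN for an
exactly closed segment); 3D convex-hull volume and surface area (coplanar
segments get volume 0 and twice the planar hull area; degenerate clouds
get NaN); mean and standard deviation of signed planar curvature in the
three projections (forward differences); curvature-scale-space signal
mean and standard deviation (section 4); and the fractal dimension
d = log(path length) / log(bounding-box diagonal).

**Degenerate steps.** Zero-length displacements have undefined headings
and are dropped from all angle-based series. A series that collapses
entirely yields NaN, which is carried as a missing-value sentinel and
median-imputed using medians fitted on training rows only.

## 4. Curvature scale space (CSS)

Each segment is projected onto the XY, YZ and XZ planes, resampled to 64
uniform arc-length bins, and smoothed with Gaussian kernels over a
geometric grid of 16 widths from 0.5 to 8 samples. At each width, zero
crossings of the curvature numerator x′y″ − y′x″ are located; the CSS
signal at a bin is the largest width at which a crossing occurs there
(0 if none). The feature set takes the mean and standard deviation of
this signal averaged over the three planes.

Numerical choices: the resampled curve is centred and scaled to unit
bounding-box diagonal before smoothing — zero crossings are analytically
invariant under translation and uniform scaling, and normalising gives a
well-defined noise floor — and the curvature numerator is zeroed below
1e-12, because raw float cancellation (~1e-19) otherwise produces
spurious random-sign crossings on exactly straight curves. The Gaussian
derivative kernels are built directly (first and second derivatives of a
normalised Gaussian, truncated at 4σ, edge-padded convolution) and match
`scipy.ndimage.gaussian_filter1d` to machine precision; they are cached
per width because the same grid is reapplied to every segment.

## 5. Feature selection

Per feature, a two-sided Mann–Whitney U test (asymptotic normal
approximation) compares male training segments with non-male screening
segments; features with p < α/n (α = 0.01, n = number of features) are
kept. Surviving features are then grouped by the transitive closure of
|Pearson r| ≥ 0.85 (union-find over the pooled training + screening
rows), and each group is represented by its smallest-p member (ties break
by schema order). The asymptotic p-value is appropriate at the operating
sample sizes (hundreds to thousands of segments per class).

## 6. One-class detector and voting

Features are standardised with statistics fitted on male training
segments only, then a one-class SVM (default ν = 0.20, RBF kernel,
γ = "scale") is fitted to the male training segments. ν upper-bounds the
fraction of training segments outside the boundary and lower-bounds the
support-vector fraction. The signed decision value is mapped through the
logistic function to a pseudo-probability for ranking metrics. A track is
called male when a strict majority of its segments is; an exact tie
resolves to non-male (the anomaly class). The track-level ranking score
is the mean segment decision value.

## 7. Evaluation protocol

Leave-2-male-trials-out: each fold holds out one unordered pair of male
trials (8 male trials → C(8,2) = 28 folds) and trains on the remaining
male trials' segments. Because the feature screen needs non-male
examples but no test data may influence any fitted state, a fixed subset
of non-male trials (default: the first 2 in sorted order) is reserved for
screening and excluded from testing; all remaining non-male and
focal-male trials are tested in every fold. Imputation medians, the
screen, the scaler and the SVM see training + screening rows only — the
test-perturbation property in the acceptance suite verifies this
invariant bitwise.

Metrics are computed at track level per fold (accuracy, balanced
accuracy, per-class and macro precision/recall/F1, ROC AUC, PR AUC for
each class and macro), averaged over folds with percentile 95% confidence
intervals, alongside a confusion matrix pooled over folds and per-label
accuracies. Ranking metrics are undefined on single-class folds and are
excluded (NaN) from the averages for those folds.

**Trial QC.** A 2D normal is fitted to each track's (duration,
displacement); trials whose track centroid exceeds the χ²(0.95, df = 2)
Mahalanobis threshold are flagged (e.g. a recording in high wind where
the whole swarm drifts). Flagging is advisory; the pipeline runner
excludes flagged trials by default (configurable).

## 8. Hyperparameter search

Exhaustive grid: ν from 0.01 to 1.0 in steps of 0.01, the four SVM
kernels, windows from 1 to 10 s in 0.2 s steps, overlaps from 0.2 to 5 s
in 0.2 s steps; combinations with overlap ≥ window are infeasible and
skipped. Scoring is track-level balanced accuracy on a held-out
validation trial set disjoint from training and screening trials.
Feature matrices are cached per (window, overlap) so ν/kernel changes
re-use the extraction. Ranking is deterministic (ties: smaller ν,
smaller window, kernel order).

## 9. Shapley attribution

The detector's signed decision value is explained by the
permutation-sampling Shapley estimator: per sampled permutation, one
background row (drawn from the male training segments) is morphed into
the explained row feature-by-feature in permutation order, and each
feature is credited with the change in the decision value when it is
switched in. Sharing one background row per draw across all explained
rows makes the scalar baseline (mean decision value over the sampled
background rows) satisfy local accuracy exactly for every row at any
sample count; the attributions converge to Shapley values (efficiency,
symmetry, dummy) at rate 1/√(samples). Output is bit-identical for a
fixed seed. Exact symmetry per finite sample holds for additive decision
functions; for interaction terms symmetry holds only in expectation.

## 10. Synthetic generator

All classes share an orbital backbone above a trial-specific centre:
radius 0.30 ± 0.05 m, angular rate 3.5 ± 0.7 rad/s with random sense,
small Ornstein–Uhlenbeck radial (0.03 m) and vertical (0.02 m) jitter,
0.002 m measurement noise, sampled at 25 Hz. Non-male classes add an OU
velocity perturbation (marginal SD 0.8 m/s × an `erraticity` knob,
correlation time 0.2 s), heavy-tailed kicks (probability 0.05 per sample,
×4), and orbital-sense reversals (rate 1 Hz × erraticity). Default
composition: 8 male trials × 14 tracks (22 ± 6 s), 6 couple trials × 20
tracks (7 ± 2 s, erraticity 1), 2 female trials × 6 tracks (6 ± 1.5 s,
erraticity 1.2), 1 focal-male trial × 5 tracks (8 ± 2 s). Focal males —
males pursuing a female — are drawn from the male flight model
(erraticity 0) with shorter durations: an earlier draft perturbed them
slightly, which contradicted the class's expected outcome, because any
nonzero OU velocity component injects high-frequency jerk content that
the selected features detect almost perfectly. At the default windowing
this sizing yields roughly 3000 male and 1100 non-male segments,
mirroring the strong class imbalance typical of field recordings. An
optional QC scenario appends male trials with a 5× angular rate and a
2 m/s downwind drift.

The generator reproduces qualitative class contrasts (orbital stability
vs erratic heavy-tailed flight, duration and segment-count imbalance) at
realistic magnitudes; it makes no claim of aerodynamic or behavioural
fidelity (no swarm interaction, chasing, or landing dynamics). The
erraticity contrast is strong: on the default dataset the cross-validated
track-level balanced accuracy is ≈ 0.94, well above what is typically
achievable on field data. A single scale factor
(`SimConfig.with_erraticity_scale`) shrinks the contrast continuously to
an indistinguishable null at 0.

## 11. Numerical choices and limitations

- **Fractal dimension is not rotation invariant.** The scaling factor is
  the axis-aligned bounding-box diagonal, which changes under rotation;
  the effect is amplified near diagonal = 1, where the logarithm in the
  denominator vanishes (the value is NaN exactly there, and unstable
  nearby). The formula is retained as published; the rotation-invariance
  property tests therefore exclude this feature.
- **Fractal dimension is unit dependent** for the same reason (the
  diagonal enters a bare logarithm); coordinates are assumed to be in
  metres throughout.
- **Kurtosis and skewness** use the biased population moments, computed
  directly from the first four moments (an order-of-magnitude speedup
  over the general-purpose wrappers at 41-sample series length, verified
  to agree to machine precision).
- **Extrema / zero-crossing counts** count strict sign changes (of the
  first difference, and of the raw series respectively); plateau samples
  do not contribute.
- **Angle clamping**: dot products are clipped to [−1, 1] before arccos
  to absorb rounding.
- **Imputation**: NaN feature values are replaced by medians fitted on
  the training + screening rows of the given split only.
- **Asymptotic Mann–Whitney p-values** are used unconditionally; for very
  small screens (tens of segments) the exact method would differ
  slightly, but the Bonferroni control property is verified empirically
  in the acceptance suite at the operating sizes.
- **Folding assumes single-label trials.** The label-permutation control
  therefore permutes the expected track labels of the evaluated
  predictions rather than re-running the pipeline on mixed-label trials,
  which the trial-wise fold planner rejects by design.
- **Couples are a single tracked entity**; the package does not model
  the pair-formation event itself, only the resulting flight signature.
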