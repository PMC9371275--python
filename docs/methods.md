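# Methods

`scoliopred` implements an end-to-end analysis for predicting the final
major Cobb angle in adolescent idiopathic scoliosis (AIS) from features
measurable at the initial presentation, together with synthetic-data
generators that make the whole chain testable without patient radiographs.
This note records the models, the parameters that matter, the numerical
choices, and what the synthetic tests do and do not demonstrate.

## 1. Landmark-based spine morphometry (`geometry`)

**Input.** Four corner landmarks per vertebra (superior-left,
superior-right, inferior-right, inferior-left) in frontal-radiograph
coordinates, for T1–L5. Internally x runs across the image and y increases
caudally→cranially; pixel input with y increasing downward is converted by
`normalize_coordinates`, which also verifies that superior corners end up
cranial to inferior corners.

**Per-vertebra geometry.** The four corners define a quadrilateral. A
five-parameter ellipse cannot be fit to four points, so the "equivalent
ellipse" is defined by the polygon's second central area moments: the
centroid is the area centroid, and the vertebral orientation is the angle
of the major principal axis of the moment tensor, reported in degrees from
the horizontal in (−90, 90]. This definition is unique, rotation-covariant,
and exact for rectangles (a rotated rectangle's principal axis co-rotates
with it — used as an analytic oracle in the tests). When the moment tensor
is isotropic (a square vertebra) the principal axis is undefined; the
orientation falls back to the superior-endplate direction and the result is
flagged. The wedge angle is the angle between the superior and inferior
endplate lines, computed with `atan2` of cross/dot products (the `acos`
form loses ~6 decimals near 0°).

**Curve detection and Cobb angle.** A natural cubic interpolating spline
x(y) is fit through the centroids (lateral position against the
cranio-caudal coordinate; arc-length parameterisation was considered and
rejected as an unnecessary complication for near-vertical spines). Curve
apices are the interior extrema of the spline whose lateral deviation from
the end-to-end centroid chord exceeds `min_deviation` (default 2 px — a
guard against numerical ripple on nearly straight spines; configurable).
Each apex is assigned to the nearest centroid (ties to the more cranial
level). For each apex, the end vertebrae are the most tilted (maximum
absolute orientation) vertebrae strictly above and strictly below the apex;
ties go to the vertebra farther from the apex (capturing the full curve
extent, and deterministic). The Cobb angle is the absolute difference of
the signed end-vertebra orientations; the convexity side comes from the
sign of the apex's lateral deviation from the chord. The curve with the
largest Cobb angle is flagged major (tie → more cranial apex).

**Known limitation.** Orientations are axis angles (defined modulo 180°),
so Cobb angles are unambiguous only while every vertebral tilt stays inside
(−90°, 90°]; clinically this covers everything short of extreme deformity.
Rigid-motion invariance is exact for rotations that keep all tilts inside
that interval.

## 2. Clinical feature encodings (`features`)

* **Flexibility** = 100·(standing − bending)/standing %, clipped to
  [0, 100] with a warning when bending exceeds standing (measurement
  noise). Scale-invariant by construction.
* **Structural rule**: a minor curve is structural when its Cobb is ≥ 80 %
  of the major's, boundary inclusive.
* **Modified Lenke type (1–6)** from the regions of the structural curves
  (proximal-thoracic T2–T5, main-thoracic T6–T11, thoracolumbar/lumbar
  T12–L4; bands configurable). A Cobb tie between structural MT and TL/L
  curves resolves to type 3 (thoracic-dominant); patterns outside the six
  types (e.g. proximal-thoracic alone) raise an explicit error rather than
  defaulting silently.
* **Risser "+"** maturity grades `0-,0+,1,2,3,3/4,4,5` map to ordinals
  0–7 in that order (open→closed triradiate cartilage, then
  iliac-apophysis coverage quartiles, start of fusion, complete fusion).
* **Feature vector**: a fixed 15-index map (documented in the module
  docstring) shared by selection, training and prediction. Categorical
  features are label-encoded in the shared matrix — adequate for tree
  ensembles; the SVM/ANN adapters one-hot expand the three nominal
  features (Lenke type, gender, brace) and standardise the rest inside
  their own pipelines, leaving the index map intact. Records with missing
  fields are rejected, not imputed (complete-case analysis).

## 3. Feature selection (`sbfs`)

Sequential Backward Floating Selection, implemented natively. From the full
set, the feature whose removal minimises the k-fold cross-validated MAE is
excluded; after each exclusion, previously excluded features are
conditionally re-included while doing so *strictly* improves the best
recorded subset of that size (standard floating-step acceptance; the
strictness guarantees termination). One seeded fold partition is shared by
every subset evaluation, so comparisons are paired; subset scores are
memoized (removal of memoization changes cost, not results). Defaults:
k = 5 folds, selection down to one feature.

Reported per subset size: mean MAE, the population SD over fold scores,
and a confidence bound equal to `ci_multiplier × SD` with default
multiplier 1.2816 (the one-sided 90 % normal quantile, matching the ~1.28
CI/SD ratio conventional in the tables this layout mirrors); the
multiplier is configurable. The best subset is the global MAE argmin; ties
prefer the smaller subset, then the lexicographically smallest index set.

Selection by cross-validated argmin has a known statistical limitation:
a noise feature whose *dataset-wide* chance correlation with the outcome
is large enough (roughly |z| > 1) genuinely reduces the CV score of that
dataset, so pure argmin selection admits such features at a rate that does
not vanish with n. A selection model that does not fit noise (e.g. a
forest with a minimum leaf size) leaves such features with exactly zero
effect on predictions, producing exact MAE ties that the smaller-subset
tie rule resolves toward exclusion; the specificity test uses such a
selector.

## 4. Progression models (`model`)

* **Split**: seeded shuffle into 75 % train / 25 % test
  (⌊0.25 n⌋ test rows).
* **Metric**: MAE = (1/n) Σ|y − ŷ| in degrees. 5° or less is the
  conventional clinical-acceptability bound for Cobb measurements.
* **Grid search**: exhaustive Cartesian product under seeded 5-fold CV
  MAE; ties go to the first combination in deterministic iteration order;
  a failing estimator scores +∞ with a warning instead of aborting.
  The default random-forest grid samples the published tuning ranges
  (trees 100–500, max_features 1–7, depth 1–50, min split 2–11, min leaf
  1–11) coarsely — 24 combinations — so a full search runs in seconds on
  one CPU; the grids are plain dictionaries and can be widened freely.
* **Families**: random forest (primary; raw label-encoded features),
  support-vector regression (RBF kernel, C = 1.0; a zero epsilon is mapped
  to a 1e-3 tube since a degenerate tube is ill-posed), a single-hidden-
  layer neural network (16 rectified units; batch size, epochs, optimizer
  tunable — the architecture is a deliberately simple stand-in), and an
  optional gradient-boosting family. SVM/ANN get the one-hot +
  standardisation preprocessing; tree ensembles do not need it.
* **Importances**: impurity-based, normalised to sum to 1, descending
  (permutation importance can be substituted by the caller; impurity
  matches the weights-sum-to-one reporting convention).
* **Prediction**: point estimate ± the model's training-CV MAE, with an
  explicit warning when any input feature lies outside its training range —
  a forest cannot extrapolate beyond the target range it was trained on.
* **Bundles**: versioned serialisation embedding the feature-index map,
  hyperparameters and seed; loading refuses version or index-map
  mismatches.

## 5. Synthetic data (`simulate`)

**Spines.** A single-bump spine's centerline is x(y) = A sin(πy/L) with
A = (L/π) tan(θ*/2), so the maximal tangent angles are ±θ*/2 and the
analytic Cobb angle is exactly θ*. Off-centre apices use two C¹-joined
quarter-waves with the amplitude solved numerically so the two end tangents
still sum to θ*; s-curves stack two opposed half-period bumps with
independent angles. Vertebrae (default 17, T1–L5) are width×height
rectangles (30×18 px on a 680 px spine) placed at equal arc-length
intervals and rotated to the local tangent; landmark noise is isotropic
Gaussian (default 0 — tests add it explicitly). Configurations whose
vertebrae would overlap are rejected. With 17 vertebrae and no noise the
measured Cobb angle is within ~0.3° of θ* across 10–90° (the outermost
vertebral centres sit half a spacing short of the maximal-tangent points).

**Cohorts.** Continuous features are truncated normals (exact inverse-CDF
sampling) with means/SDs/ranges emulating a published surgical AIS cohort
of 193 patients (initial major Cobb 48.9 ± 13.9°, range 10.9–99.5°, and so
on); categorical features follow that cohort's frequencies (169 F / 24 M,
Lenke-type and apex-location tables, eight Risser "+" grades). Two printed
summary rows are internally inconsistent in the source (apex wedge
56.7 ± 4.1 with range 0–21°; flexibility 57 ± 19.3 with range 0.05–0.99);
the generator trusts the *ranges* — wedge ~ TN(10.5, 4.1, [0, 21])°,
flexibility ~ TN(57, 19.3, [5, 99]) % — and this uncertainty is flagged
here. Age at last visit is derived (age at first + time span), which makes
the three age-related columns exactly collinear by construction — only
coefficient sums along that direction are identifiable, as the recovery
test asserts.

**Outcome model.** final Cobb = initial Cobb + Δ with

    Δ = 10.5° + 4.0·z(initial Cobb) − 2.0·z(flexibility)
        + 1.0·z(lordosis) + 0.9·z(kyphosis) + 0.8·z(age last)
        + 0.6·z(levels) − 0.45·z(Risser) + ε,   ε ~ N(0, σ=4°),

where z(·) standardises by the configured marginal mean/SD. The intercept
10.5° is the emulated cohort's mean progression (59.4° − 48.9°); the
coefficient ordering and the dominance of the initial Cobb angle (which
additionally enters through the structural `initial + Δ` term) mirror the
importance ranking reported for the real cohort; the magnitudes were fixed
once so that the irreducible MAE σ·√(2/π) ≈ 3.19° leaves clear headroom
under the 5° clinical bound while progression remains multi-factor.
σ = 4° keeps the noise floor below that bound. The final angle is floored
at 25° (surgical-cohort floor; disable with `clip_floor=None` for exact
coefficient-recovery checks). An optional initial-Cobb × flexibility
interaction (default 0) lets users probe the forest's advantage over
linear baselines. Features are drawn independently (a real cohort
correlates Risser with age, flexibility with curve size, ...); a
correlation hook is future work.

**What passing tests show.** The synthetic cohort demonstrates that the
pipeline recovers a known effect structure and achieves the expected error
given its own noise model; it does *not* demonstrate clinical performance —
real radiographic landmarks have structured (not isotropic) error, real
features are correlated and non-Gaussian, and real progression is not
linear in standardised features.

## 6. Pipeline, sizes and determinism (`io`, `cli`)

The end-to-end run (`run_pipeline`, CLI `scoliopred pipeline`) chains:
cohort (generated or loaded) → 75/25 split → SBFS on the training split
(selection on the full cohort is available behind a flag but leaks
information from the test split and is off by default) → grid search →
final forest → held-out evaluation. Every stage's seed is derived from the
single top-level seed via sha256("{seed}:{stage}") truncated below 2³¹, so
stages are independently reproducible and reruns are byte-identical
(provenance records the config hash, stage seeds and library versions; no
timestamps). The selection-time forest uses 30 trees by default (20 in the
headline replicates) — selection needs only a stable *ranking* of subsets,
for which a small paired-fold forest suffices; the final model is tuned
over the full grid. Problem sizes throughout (193-patient default cohorts,
10 headline replicates, 24-point grids) are chosen so a complete analysis
runs in minutes on a single CPU.
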