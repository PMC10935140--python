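# Methods

This note documents the models, the defaults that matter, the numerical
decisions, and what the synthetic corpus does and does not show.

## Harmonization model

The canonical recording is a uniform time grid with triaxial acceleration
in g, triaxial angular velocity in rad/s, and a per-sample binary label
(0 = activity of daily living, 1 = fall). Heterogeneous sources are
reduced to this form by:

- **Unit unification.** Acceleration in m/s² is divided by standard
  gravity (9.80665 m/s² per g); angular velocity in deg/s is multiplied
  by π/180. Conversions are exact scalings and round-trip to 1e-12
  relative.
- **Resampling.** "Subsampling to the lowest common rate" is implemented
  as linear interpolation onto a uniform 18 Hz grid spanning
  [t₀, t_end], with floor((t_end − t₀)·18) + 1 output samples. This
  handles both 20→18 and 50→18 uniformly, preserves duration within one
  output period, and reproduces affine signals exactly. No anti-alias
  filter is applied by default: the downstream features are dominated by
  low-frequency posture and impact content, and none of the source rates
  is near an integer multiple of the target. Labels are categorical and
  cannot be interpolated; each output sample takes the label of the
  nearest original sample.
- **Invalid files.** A trial containing any non-finite sensor or label
  value is removed whole (files, not rows, are the unit of curation);
  each removal is logged.
- **Normalization.** Optional per-channel min-max mapping onto [-1, 1].
  Two fitting scopes are provided: `per_dataset` (fitted over all of a
  dataset's recordings — the conventional whole-corpus variant, which
  leaks test-set ranges into training and is therefore tagged on every
  report that uses it) and `fit_on_train` (fitted on the training
  partition only, the methodologically sound variant). Constant channels
  map to 0, the midpoint, avoiding division by zero; normalization is
  idempotent to 1e-12.

## Windows and features

2 s windows with 50% overlap (36 samples / 18-sample stride at 18 Hz);
trailing partial windows are discarded. A window's label is the mode of
its per-sample labels; an exact tie resolves to *fall*, the
sensitivity-first choice for a detector. Thirteen statistics per channel
(78 features) with fixed definitions: population standard deviation;
skewness m₃/m₂^{3/2} and non-excess kurtosis m₄/m₂² (both 0 when m₂ = 0);
energy = mean of squared values (mean signal power — by Parseval this
equals the spectral energy up to normalization, which is how "frequency
content" enters these otherwise time-domain features); RMS = √energy;
zero crossings counted as strict sign changes of the raw
(non-mean-centered) signal, zeros not counting; quartiles by linear
interpolation; autocorrelation at lag 1 (the standard serial-correlation
estimator with the full-window variance in the denominator; 0 for
constant windows). Every definition is pinned by tests against
independent scipy/statsmodels implementations.

## Feature selection

Stage 1 fits a 200-tree random forest (seeded) and ranks features by
normalized mean-decrease-in-impurity (Gini) importance; ties break
lexicographically by feature name, and column order is canonicalized
before fitting, so selection is invariant to the caller's column order.
Features above the mean importance survive. Stage 2 re-scores the
surviving candidate set under 5-fold subject-disjoint CV with a 100-tree
forest, excluding one feature at a time; the exclusion delta is the mean
drop in CV accuracy.

The default keep rule is **keep-unless-harmful**: a feature is dropped
only when its mean exclusion delta is below −2 standard errors of the
per-fold deltas. The stricter "keep only strictly positive deltas" rule
is available (`positive_delta`) but is a poor default for correlated
feature sets: a pair of near-duplicate informative features gives each
member an exclusion delta of exactly zero, so strict positivity discards
*both* copies and, on realistic matrices, collapses the selection to one
or two features. Measuring deltas against fold-level noise keeps
redundant-but-informative features while still rejecting features whose
removal genuinely helps. Plain (not balanced) accuracy is the default
ablation score, matching the selection stage's conventional use;
balanced accuracy is a flag. If the rules eliminate everything, the
top-ranked feature is kept with a warning.

## Class weights and detectors

With n windows of which n_c are class c, the inverse-class-frequency
weight is ω_c = n/(2 n_c) — normalized so a balanced corpus gives
ω = 1 for both classes. Weights are computed as exact rationals, so the
fall:ADL weight ratio equals n_ADL/n_fall with no float rounding. The
literal class-frequency rule ω_c = n_c/n (which up-weights the
*majority* class) is retained behind `scheme="class_frequency"` for
comparison; it contradicts the stated intent of cost-sensitive fall
detection and is not the default.

- **Weighted SVM.** Soft-margin SVM whose per-sample slack penalty is
  C·ω_{y(i)}, implemented via per-class weights on scikit-learn's SVC.
  Kernel default RBF with gamma = 1/(p·var) ("scale"); C = 1. Because
  only the products C·ω enter the objective, doubling all weights while
  halving C leaves the decision boundary unchanged (tested). Scores are
  the signed margin; label rule: score > 0 → fall.
- **Weighted ANN.** One hidden layer (64 tanh units by default), sigmoid
  output, minimizing J = (1/2n) Σ ω_{y(i)}(ŷᵢ − yᵢ)² by full-batch
  gradient descent (learning rate 0.5, momentum 0.9) with seeded Xavier
  initialization and early stopping on a stratified 15% validation split
  (patience 60). The absolute scale of the 1/2n factor is absorbed by
  the learning rate; only the weight *ratio* is meaningful. With
  momentum 0 and a small learning rate the training loss is
  non-increasing (tested). Scores are the sigmoid output; label rule:
  score ≥ 0.5 → fall.
- Both detectors standardize their input features internally (fitted on
  the training partition); this is a conditioning choice inside the
  model, independent of the corpus-level [-1, 1] normalization mode.
- **Threshold baseline.** A window is a fall iff its peak acceleration
  norm (raw, in g) reaches the threshold (default 2.5 g). Sweeping the
  threshold over the observed peaks yields the baseline's ROC and
  balanced operating point.

## Evaluation

Cross-validation is grouped at the (dataset, subject) level: distinct
subjects are shuffled with the seed and dealt round-robin into k = 10
folds; when labels are supplied, shuffling is retried (bounded) until
every fold's test split contains both classes. k is reduced to the
subject count, with a warning, for small sources. Metrics: recall,
specificity, precision, F1, accuracy (zero-denominator ratios reported
as 0 with a warning), AUC-ROC on continuous scores, and maxSeSp — the
max over all score thresholds of min(sensitivity, specificity), a
balanced-operating-point summary. maxSeSp is computed from the full ROC
without convex-hull simplification, because the balanced point can sit
at an operating point that hull pruning would discard. Metrics are
computed per fold and then averaged (mean ± std across folds); fold
entries undefined on a single-class test split are recorded as missing
and excluded from the mean. Cross-dataset experiments train on one full
source and evaluate once on the pooled held-out sources (no CV), with
the held-out pool rather than per-dataset averaging as the default.

## The synthetic corpus

The generator emulates the *structural* obstacles of multi-source
wrist-IMU fall corpora, not wrist biomechanics. Defaults (the study
conditions used by the tests and the acceptance script): three sources —
18 Hz with g/rad-s, 20 Hz with m/s²/deg-s, 50 Hz with g/rad-s — each
with 12 subjects, 5–7 activities (walking, standing, sit-stand
transitions, clapping-like high-frequency spikes, runs; 1–3 fall types),
3 trials per activity, 15 s per trial. That is 648 trials and 9072
windows; real corpora of this kind have 17–25 subjects per source, and
the subject count here was set at 12 to keep grouped 10-fold experiments
comfortably sized while leaving more subjects than folds.

ADL trials are gravity along a slightly tilted body axis plus sinusoidal
movement and white noise. Fall trials are piecewise: pre-fall movement,
a half-sine impact whose crest reaches exactly `impact_peak` (2.7–3.3 g
across the default fall types; the bump dominates sensor noise at the
crest), a lying segment with gravity rotated by the configured
orientation change, and a ~1 s recovery back to upright quiescence —
mirroring simulated-fall protocols in which the volunteer gets back up.
Labels are 1 over the impact plus the lying segment (2.5 s by default).
The label span doubles as the lying duration deliberately: if the trial
lay still beyond the labeled span, those unlabeled samples would be
signal-identical to labeled fall samples and no detector could separate
the classes; and labeling a much longer tail would push the windowed
fall prevalence far above the few-percent regime that makes the
imbalance problem real. With the defaults the per-source fall-window
prevalence lands at roughly 4.2/7.1/9.1% (band checked at generation
time, warning outside 2–10%).

What passing tests therefore show: the harmonization arithmetic, the
feature definitions, the weighting scheme, the leak-free CV machinery
and the end-to-end plumbing are correct, and the cost-sensitive learners
dominate a magnitude-threshold rule on a corpus with realistic structure
and imbalance. What they do not show: performance on real falls — the
synthetic classes are more separable than real wrist data (no sensor
artifacts, no confounding high-impact ADLs like hand-hammering, no
inter-subject kinematic diversity beyond amplitude scaling), so absolute
metric values here exceed what heterogeneous real recordings yield, and
the generalization experiments degrade only when the fall kinematics are
deliberately shifted across sources.

## Degenerate inputs and tie-breaks (summary)

- Window label ties → fall; empty windows are an error.
- Zero-variance windows: skewness, kurtosis, autocorrelation, std → 0.
- Constant channels normalize to 0; refitting normalization on already
  normalized data is a no-op.
- Importance ties → lexicographic feature order; empty selection →
  top-1 fallback with a warning.
- Single-class label vectors are rejected by weight computation,
  ranking, AUC and maxSeSp; single-class *fold test splits* yield
  missing AUC/maxSeSp entries, excluded from aggregates with a warning.
- Ablating the only candidate feature compares against the featureless
  majority-class predictor.
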