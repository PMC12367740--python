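# Methods

This note documents the models, the synthetic data they are exercised
on, and the numerical and design choices a maintainer would want to
know. Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## The synthetic cohort generator

`stroketriage.cohort` emulates an EMS stroke-code registry. Defaults of
`CohortSpec`:

| parameter | default | meaning |
|---|---|---|
| `p_hemorrhagic` / `p_ischemic` / `p_other_or_missing_label` | 0.1470 / 0.6187 / 0.2343 | episode label mixture (sums to 1) |
| `p_lvo_given_ischemic` | 0.5063 | LVO prevalence among ischemic episodes |
| `lvo_sex_skew` | 0.57 | female share **among LVO-positive** cases |
| `age_model` | skew-normal per subtype | ischemic loc 84 y, scale 12, skew −4 → mode ≈ 78 y; hemorrhagic flatter (loc 78, scale 16, skew −2) |
| `effect_sizes` | ±1.0 SD | planted LVO shifts, see below |
| `missingness_rates` | scale 0.244, vitals 0.10, ordinals 0.05 | MCAR per variable |
| trend params | HR 80±15, SpO₂ 96±2.5, SBP 135±20, DBP 80±12 | population baseline mean ± SD; within-episode noise 3 / 0.8 / 5 / 4 |

The `lvo_sex_skew` wording is ambiguous in the field (female share of
LVO vs LVO rate among females); it is implemented as the former and is
configurable. Internally P(LVO | ischemic, sex) is derived by Bayes'
rule from the overall rate and the skew.

**Planted effects.** Four variables carry a mean shift between LVO
classes among ischemic episodes: systolic pressure +1.0 SD, heart rate
+1.0 SD, arm strength −1.0 SD (on the latent severity scale), SpO₂
−1.0 SD. The vital-sign shifts are applied to the *per-episode
baseline*, so every summary statistic of that vital (min, mean, median,
…) moves together; "recovering the planted minimum systolic pressure"
therefore means any systolic summary ranking highly in attribution.
One full standard deviation per variable is the package's definition of
a *strong* planted signal: it puts the Bayes-optimal AUC of the
four-variable signal near 0.92, high enough that a correct
implementation separates clearly from a broken one, low enough that the
task is not trivial. Hemorrhagic episodes additionally present with
worse consciousness (−0.6 SD latent), higher systolic pressure
(+0.7 SD), and enriched antihypertensive/anticoagulant flags, so the
subtype specialists also have signal to find.

**What the generator does not emulate.** Vitals are conditionally
independent given the labels (no covariance structure between heart
rate and pressure), trends are stationary Gaussian noise around a
baseline (no drift, artifacts, or monitor dropouts), missingness is
MCAR by default (a MAR hook conditioned on severity exists but is off),
and text flags are generated directly rather than via free text.
Passing tests therefore demonstrate that the *pipeline machinery* is
correct and that planted signal of a stated size is recovered — not
that any particular performance level will hold on real EMS data.

Ordinal clinical findings use 4-level codes, 0 = worst … 3 = normal,
with a distinct "Not Evaluated" code (−1) introduced at encoding time —
non-assessment is its own state, not a severity level. "Most severe"
during duplicate resolution is the numerically lowest non-negative code.

## Assembly

Trend summarization emits mean, median (midpoint rule for even length),
min, max, delta = max − min, and variation rate = (last − first) /
duration in units per second — the net-drift reading of "variation
rate"; delta captures excursion separately. The source merge joins on
patient id with a same-calendar-day timestamp tolerance (the sources
carry timestamps but no stated window), keeps episodes with a
non-missing subtype label and at least one informed feature, and never
imputes: the missingness mask is conserved into the master dataset.
The completeness cascade's default cutoff grid is {1.0, 0.75, 0.5,
0.25, 0.1, 0.05}; the 5% floor triggers a warning, not an error. Tier
nesting (fewer variables ⇒ more fully-informed episodes) is a structural
invariant and is tested as such.

## NSGA-II feature selection

Objectives: minimize selected-feature count, maximize mean 3-fold
stratified CV score of the wrapped classifier on the masked features.
Choices where the standard scheme leaves freedom:

- **Crossover** is uniform at rate 0.9; **mutation** flips each bit with
  probability 0.02; empty masks are repaired by setting one random bit.
- **Annihilation** replaces the worst ⌈0.1·population⌉ offspring with
  fresh random masks each generation (diversity injection).
- **Elite replacement** copies up to 2 archived best-ever individuals
  over the worst surviving offspring.
- The **reported front** is the non-dominated set over *all* masks ever
  evaluated (an archive), deduplicated per objective pair. This makes
  the front's hypervolume non-decreasing by construction and makes the
  result comparable across search seeds.
- The CV folds used to score masks are seeded by `cv_seed`,
  deliberately separate from the search seed: the objective landscape
  is then identical across search seeds, so two runs can disagree on
  their path but must agree on the true front when the budget is
  exhaustive. Mask evaluations are cached by bit pattern.
- Redundancy among selected features is handled implicitly by the count
  objective; an explicit pairwise-correlation penalty was considered
  and left out of the default because it introduces a weighting
  constant with no principled value.
- Default budget (population 40, 30 generations) is a desk-scale
  choice. The pipeline's `select` stage scores masks with a shallow
  decision-tree surrogate by default (`ga_wrapped_model="surrogate"`);
  set `"reference"` to wrap each task's reference model at ~30× cost.

## Classifiers

Preprocessing: identifiers dropped; numerics median-imputed with a
missing-indicator column, then standardized (constant columns map to 0);
categoricals most-frequent-imputed and one-hot encoded. Imputation is
confined to this model-facing transform — the master dataset keeps its
missing values. SMOTE (k = 5, parity target) interpolates minority rows
toward one of their k nearest minority neighbours and is applied to the
hemorrhagic task's training folds only. Hyperparameter search is
budgeted random search over per-family grids with 3-fold CV;
`search_method="bayesian"` is accepted in the config surface but
unimplemented (no Bayesian-optimization backend is declared as a
dependency) and raises. CV summaries report mean, SD, and a
normal-theory 95% CI (mean ± 1.96·SD/√folds) — with 3 folds this is a
coarse description, not an exact interval.

The 70/30 stratified split uses floor(n·0.7) training rows with
per-class counts within ±1 of proportionality (489 → 342/147).

## Fusion and cascade

The combiner is a two-feature Gaussian Naive-Bayes over the specialists'
positive-class probabilities — the simplest probabilistic construction
that consumes both outputs. Likelihood variances are floored by the
Gaussian-NB smoothing term; priors are clipped to [1e−9, 1−1e−9] so a
degenerate prior of 1.0 behaves as a limit rather than a log(0). The
prior grid (default 0.05…0.95 in steps of 0.05) is scored on an inner
30% validation fold by the *minimum* of {ischemic precision, ischemic
recall, hemorrhagic precision, hemorrhagic recall} — a max-min reading
of "balancing precision and recall for each class"; ties go to the
smaller prior, and posterior ties at 0.5 resolve toward ischemic
(safety-first: the costlier miss is an untreated occlusion). The LVO
gate threshold defaults to 0.5.

The baseline `ScaleDefinition` shipped by `default_scale()` is a
**synthetic placeholder** (deficit scores on arm strength, facial
paralysis and consciousness, positive at ≥ 4): the true item content of
the regional prehospital scale is published elsewhere and must be
configured by the user for any clinical comparison. The scale returns
"missing" whenever any required item is uninformed, mirroring the
upstream scale missingness.

## Evaluation

- Undefined metric ratios (zero denominators) are reported as absent,
  never as 0. Bootstrap resamples on which a metric is undefined are
  skipped and counted.
- The equalized-odds difference is max(TPR gap, FPR gap) over groups —
  the convention under which an FPR spread of 100% vs 0% yields exactly
  1.0. Groups lacking positives or negatives are excluded from the
  summary with a logged note.
- Calibration uses 10 equal-width bins on [0, 1], empty bins omitted.
- Quantile binning delegates to pandas `qcut` with duplicate boundaries
  dropped (fewer bins with a warning when values tie).
- Mann–Whitney U uses exact enumeration for untied samples of ≤ 8 per
  side and the tie-corrected normal approximation otherwise; the
  chi-squared test applies no continuity correction (matching the
  hand-computable Pearson formula).
- `recover_matrix_from_metrics` reconstructs a confusion matrix from
  published rounded percentages by integer search; because scalar
  multiples of a matrix share every metric, uniqueness is enforced up
  to scaling and the primitive (gcd-reduced) matrix is returned.
- Feature attribution defaults to permutation importance (mean AUC drop
  over shuffles, negative drops floored at 0); a `shap_library` method
  delegates to the shap package when installed.

## Pipeline

One global seed derives per-stage seeds by fixed offsets (simulate +0,
split +1, select +2, train +3, fuse +4, evaluate +5), so any stage can
be re-run in isolation. Every tabular artifact is CSV with JSON
manifests; `report.json` contains no timestamps or timings and two runs
with identical config and seed are byte-identical (timings live in
`manifest.json`, alongside SHA-256 checksums of all artifacts). The
smoke configuration used in tests (300–500 episodes, GA population
12–20 over 4–10 generations) was sized so a full run completes in
seconds; scale `n_episodes` and the GA budget up for real experiments.

## Known limitations

- The hemorrhagic specialist inherits the hard problem of rare-event
  detection; SMOTE mitigates but does not solve it, and fusion quality
  is bounded by the weaker specialist.
- The generator's independence assumptions make feature-selection tasks
  easier than on real registries with collinear vitals.
- Bayesian hyperparameter optimization and reweighting-based bias
  mitigation are out of scope; so are waveform-level ECG features and
  proprietary monitor formats (trends enter as CSV).
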