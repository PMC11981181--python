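# Methods

## Screening problem and data model

Each participant (age ≈ 5 y) copies four shapes on a pen tablet after
watching a demonstration. A recording is a 30 Hz multichannel series:
pen-tip x, y (relative screen coordinates in [0, 1]), pressure [0, 1],
azimuth [0, 360), tilt [0, 90], and gaze rotations about the X/Y axes
[−90, 90]° (missing values allowed; the gaze estimate comes from facial
video, not an eye tracker). Demonstration-phase recordings additionally
carry the advancing-line tip (`line_x`, `line_y`) the child watches.
Ground truth is the parent-rated SRS-2 T-score; the high-trait group is
defined by the sex-specific screening cutoffs for Japanese preschoolers
(boys > 53.5, girls > 52.5 — half-point cutoffs, so integer scores never
tie).

## Segmentation

All pen features are computed inside *active drawing segments*: maximal
runs of samples with pressure strictly above a threshold (default 0: any
contact) and length ≥ 3 samples (0.1 s), discarding spurious taps. No
first difference is ever taken across a segment boundary, so pen-up gaps
cannot leak into change statistics. Threshold and minimum length are
config-exposed because the original preprocessing rule is not published
in the main text; whether leading/trailing idle time is trimmed per
stroke or per task is likewise configurable at ingestion.

## The 16 variables

Pooled over active samples: mean and sample SD (n−1) of pressure; mean
and SD of drawing speed, where speed between consecutive pen-down
samples is Euclidean distance / Δt; mean, SD of tilt. "Mean change"
features (pressure, speed = acceleration, tilt, orientation) are means
of **absolute** per-sample first differences: signed differences
telescope to ≈ 0 and carry no information about instability, which is
what these variables are meant to capture. A signed variant is
config-switchable for sensitivity analysis.

Azimuth is a circular quantity; its statistics use the circular mean
(direction of the mean resultant), circular SD √(−2 ln R) in degrees,
and first differences wrapped to (−180, 180] before taking absolute
values — a 350°→10° step counts as 20°, not 340°. Naive linear
statistics on raw angles remain available (`orientation_stats: linear`)
since the original analysis may have used them.

Gaze coupling is the zero-lag Pearson correlation between a gaze channel
and its reference: the advancing line over all demonstration frames, or
the pen tip over pen-down samples while drawing, horizontally and
vertically (4 features). Pairs with missing gaze are dropped pairwise;
fewer than 10 valid pairs or zero variance flags the feature invalid and
imputes 0 ("no linear coupling"), keeping the design matrix complete
while the validity mask records the imputation.

## Classifier and model selection

Linear soft-margin SVM (hinge loss, L2 regularization, liblinear
formulation with the bias as an augmented regularized feature), solved
by deterministic dual coordinate descent; the solver is cross-checked
against liblinear to ~1e-9 in the test suite and exists because wrapper
selection inside nested cross-validation needs ~10⁶ fits of 100-row
problems, where per-call overhead of a general-purpose library dominates.

Features are z-scored **inside every fold** using the training rows
only. Standardization matters: a cost of 10⁻³ is only meaningful on
unit-scale features, and per-fold scaling keeps LOOCV leak-free and
makes the whole procedure invariant to feature units (verified by test).
No class weighting is applied; on an 85:15 imbalance an unweighted fit
naturally produces the high-specificity operating point the screening
setting favors.

Model selection searches feature subsets and the cost grid
{10⁻³, 10⁻², 10⁻¹, 1, 10} jointly, maximizing LOOCV accuracy with ties
broken by higher sensitivity, then fewer features, then lower cost.
The default strategy is sequential floating forward selection capped at
8 features (the published shape models used 4–8 variables); exhaustive
enumeration is available for ≤ ~10 candidates and serves as an upper
bound on the greedy search in tests. The search is deterministic:
candidates in column order, costs ascending, strict-improvement
replacement only.

Probabilities use Platt scaling fitted per fold on the fold's own
training decision values (regularized targets keep the slope finite on
separable folds; Newton iterations with backtracking, deterministic).

**Selection optimism.** Reporting the LOOCV accuracy that the search
itself maximized is optimistically biased. `nested_loocv` reruns the
entire search inside every outer fold, giving an estimate unbiased by
selection, and `selection_optimism` reports both numbers and their gap.
On imbalanced null data the search often cannot beat the majority rate,
so the gap can legitimately be 0; it is reported, not assumed positive.
The outer loop can be evaluated on a stratified random subsample of
folds (a Monte Carlo estimate of the same quantity) to bound runtime;
the acceptance audit uses 40 of 133 outer folds.

## Shapley interpretation

For a linear decision function with an interventional (independent)
background expectation, Shapley values have the closed form
φ_ij = w_j (x_ij − mean_bg(x_j)), exact — no sampling. Attributions are
computed on the decision function, not the calibrated probability, so
local accuracy (base value + Σφ = decision value) holds to machine
precision, and the background is the full training cohort. Ranking is
by mean |φ|, ties alphabetical.

## Synthetic cohort generator

The generator exists so the entire pipeline is testable end-to-end with
known ground truth. Group structure enters through **latent
per-participant targets**: for each of the 12 pen features, a
participant's target is drawn from a population distribution
(`LATENT_BASE`) shifted by a standardized effect d (`effect_map`) for
the high-trait group. The time-series realization then hits those
targets: speeds, pressure, tilt and azimuth are stationary AR(1) series
whose lag-1 correlation is set from the target mean-absolute-change via
E|Δz| = σ√(2(1−ρ))·√(2/π), and each realized series is re-standardized
over the pen-down samples so the extracted SD equals its target exactly
(otherwise the sample SD of a smooth AR(1) fluctuates ~30% per
recording and dilutes planted effects about twofold). Strokes follow
the four shape templates (sun = 36-gon circle + 8 rays) with pen-up
gaps of 0.2–0.5 s at exactly zero pressure; demonstration recordings
trace the template uniformly over the published demonstration durations
(16/14/15/23 s).

Gaze is constructed by exact Gram–Schmidt mixing on the reference
frames, so the sample correlation with the pen (or line) equals the
participant's coupling target exactly; couplings get a per-recording
wobble (SD 0.05) so the four correlation features are related but not
copies. SRS-2 scores are drawn per group as a gamma-distributed excess
beyond the sex cutoff (moment-matched to 68.15 ± 23.68 high,
32.06 ± 11.26 low), so group labels always satisfy the cutoff rule by
construction; a cutoff-truncated normal could not reach the high
group's published SD (a lower-truncated normal with mean ≈ 68 above a
cutoff of ≈ 54 caps out near SD 14 — the real high group is
long-right-tailed). Ages are Normal(5.05, 0.17) truncated to
[4.5, 5.5].

Default effect sizes are not identifiable from published results (no
per-feature group summaries exist); they were fixed once at values that
encode the strong separability the screening models are reported to
achieve — d between 0.5 and 1.8 on the pen features, with signs from
the motor-control literature (harder/less steady pressure, slower and
jerkier movement, less stable pose), and gaze–pen coupling 0.40 (high)
vs 0.75 (low) with between-participant SD 0.15. `null_spec()` zeroes
every effect for calibration work.

**What the generator does *not* emulate:** redraw-after-deviation
events, OpenFace estimation error structure (gaze noise is white
Gaussian), pen-tablet quantization, within-task fatigue drift, or any
correlation between SRS-2 score and drawing behavior beyond the group
shift. Passing tests therefore demonstrate correctness and calibration
of the *pipeline*, not field performance on real recordings.

## Numerical choices and degenerate inputs

- Sample (n−1) SDs throughout feature extraction; the solver tolerance
  is 1e-8 on the maximal projected-gradient violation, 1000 passes max.
- Zero-variance columns standardize with scale 1 (no NaNs).
- Single-class training folds (possible only when a class has one
  member) predict the training class and are counted and warned about.
- Circular SD of a zero-resultant sample is +inf by convention; constant
  angles give exactly 0.
- Invalid correlations impute 0 and are flagged, never silently dropped.
- All randomness flows from `numpy` SeedSequence spawning in a fixed
  order, so identical spec + seed reproduce byte-identical cohorts.

## Problem sizes used by the checks

The acceptance checks run at the study scale (133 participants, four
shapes) for model selection; the planted-recovery property uses 40/80
participants and one shape per seed — large enough that omitting a
planted d = 3 feature measurably costs LOOCV accuracy, which is what
makes subset recovery a consequence of accuracy maximization — and the
null calibration audit evaluates 40 stratified outer folds of the
133-participant null cohort.

## Known limitations

- The wrapper search reproduces the published *procedure class*, not
  necessarily the published selected subsets: the supplement's exact
  search algorithm and criterion are not public, and LOOCV-accuracy ties
  make selected subsets sensitive to scan order.
- The published cohort-table χ² (0.474) is not reproducible from the
  printed counts by the standard Pearson formula (0.513) or with
  continuity correction (0.224); the package reports the standard value.
  Likewise the published age t (1.273) differs slightly from the value
  implied by the rounded printed summaries (1.212); only its df is
  asserted.
- Platt calibration on perfectly separated folds is regularized but
  still saturates; probabilities near 0/1 should not be over-read.
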