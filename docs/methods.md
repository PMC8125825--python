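# Methods

## Signal model and features

Input is a synchronized six-sensor gyroscope recording: placements LW, LT,
LI, RW, RT, RI (left/right wrist, thumb, index), triaxial angular velocity in
deg/s at a common sample rate. No filtering, detrending or sensor fusion is
applied; the accelerometer, if present in a file, is carried but unused.

For a repetition window `[t_start, t_end)` (half-open, so consecutive windows
concatenate without double-counting a sample):

* per-sensor mean speed = time-average of the per-sample Euclidean norm of
  the angular velocity vector. Averaging the norm rather than the vector is
  deliberate: averaging the vector first would cancel oscillatory motion and
  drive every mean toward zero.
* hand mean = arithmetic mean of the three per-sensor means of one hand;
  fingers mean = mean of the thumb and index means. Because sampling is
  synchronized and uniform, averaging per-sensor means equals averaging the
  aggregate signal first; the test suite asserts this equivalence.

Features per repetition:

* **HR** = max(hand means) / min(hand means) ≥ 1.
* **FWR** per hand = fingers mean / wrist mean. Two variants are always
  stored: `fwr_active`, the FWR of the most active hand (the label-free proxy
  for the moving hand in stabilizing-hand tasks — at inference time the
  dominant hand is unknown), and `fwr_mean`, the average of the two hands'
  FWRs (for tasks where both hands work).

Degenerate inputs: denominators below ε = 1e-9 deg/s yield +inf, which
compares greater than any finite cutoff (an idle stabilizing hand therefore
routes toward "unimanual", the right limit). An exact tie in hand activity
breaks toward the right hand; this is a probability-zero event on real data
but keeps the pipeline deterministic.

## Cutoff learning

Each tree branch is a binary ROC problem with the rule
`score > threshold → positive`:

| cutoff           | subset                      | score        | positive class    |
|------------------|-----------------------------|--------------|-------------------|
| `hr_unimanual`   | all repetitions             | HR           | unimanual         |
| `hr_stabilizing` | bimanual only               | HR           | stabilizing hand  |
| `fwr_stab`       | stabilizing-hand bimanual   | `fwr_active` | finger activity   |
| `fwr_both`       | both-hands bimanual         | `fwr_mean`   | finger activity   |

Candidate thresholds are the midpoints between adjacent distinct scores plus
±inf sentinels; the alternative `observed-value` convention is available as a
parameter since published threshold values cannot disambiguate which was
used. Rates are computed by exact counting, AUC by the trapezoid over the
curve (equal to the Mann–Whitney pairwise probability with ties counted ½),
and the working cutoff maximizes Youden's J with ties broken toward the
larger (more specific) threshold. If the scores carry no information, the
+inf sentinel is returned with a warning. Orientation is fixed per branch to
match the tree's inequalities; there is no automatic orientation detection
and no cost weighting.

## Classification and evaluation

`classify` applies the three steps with strict `>` at every cutoff; equality
falls to the lower branch. This choice is not forced by the published
inequalities (stated only as "greater than") and is fixed for determinism.

`evaluate` reproduces the green/red per-criterion accounting: each repetition
is checked against the inequalities its *true* category requires at each
applicable step (unimanual repetitions have only step 1), and is
overall-correct iff all of them hold. For a repetition that would be routed
down a wrong branch this differs from `classify(x) == truth`, so the
conventional confusion-matrix view is also reported; on data without
borderline cases the two views coincide (asserted by test). Accuracy tables
pool repetitions within an activity or category rather than averaging
per-activity percentages — the pooling choice is documented here because the
alternative is equally defensible when repetition counts differ.

One published inconsistency is worth noting: the reference per-repetition
table lists two different HR values for one writing repetition at steps 1
and 2 (20.13 vs 27.54) although both columns are the same quantity. This
package computes a single HR per repetition; the embedded reference table
stores the step-1 value (20.13), under which that repetition passes all
three criteria.

`loso_cv` holds each participant out in turn, learns cutoffs from the rest
(a training split missing a category raises an error naming the fold), and
pools all held-out repetitions into summary tables.

## Synthetic data generator

The generator works backwards from the classifier's inputs. Per repetition
it draws target HR, per-hand FWR and active-hand wrist speed from
category-specific ranges, solves for the six per-sensor mean speeds that
realize those targets exactly (thumb and index share their hand's fingers
target), and synthesizes each sensor as smoothed-noise norm bursts rescaled
so the empirical time-averaged norm equals its target (exact up to float
rounding; tolerance 1e-3 asserted). Axes are filled isotropically with
random unit directions — the pipeline consumes only norms, so axis realism
is secondary and exact rescaling keeps tests sharp.

Defaults and why:

* `well_separated` preset: unimanual HR ∈ [30, 90], stabilizing HR ∈ [6, 18],
  both-hands HR ∈ [1, 3]; finger-branch FWR ∈ [2.6, 6], global-branch
  FWR ∈ [1.2, 2.1]; stabilizing/idle-hand FWR ∈ [0.8, 1.6]; wrist speed
  ∈ [20, 80] deg/s. The ratio bands bracket the values reported for real
  activities of each category; the disjoint gaps (18–30, 3–6, 2.1–2.6) make
  parameter recovery exact, so this preset is the pass/fail regime.
* subject random effects: lognormal, σ = 0.08 on ratios and σ = 0.20 on
  speed; repetition noise σ = 0.05 on ratios. Effects act in log space and
  draws are clipped back to the category range, so separated presets keep
  disjoint supports by construction — which is exactly what makes learned
  cutoffs provably land in the inter-class gaps.
* `realistic` preset: overlapping ranges (e.g. unimanual HR from 14,
  stabilizing HR up to 30, finger FWR from 2.0 vs global up to 2.8) and
  larger variability (σ = 0.18 / 0.12), emulating borderline activities such
  as writing. Accuracy under it is preset-dependent, so it is provided for
  exploration, not for pass/fail tests.
* sample rate 100 Hz by default; the recording instrument this emulates
  samples at 500 Hz, and the rate is a parameter, not a constant. Repetition
  durations are drawn from [4, 8] s, capped at the 25 s protocol maximum;
  repetitions are separated by 5 s low-activity rest (mean norm 0.5 deg/s).
  Each subject is right-dominant with probability 0.9.

What the generator does **not** emulate: biomechanically plausible axis
trajectories, accelerometer content, sensor drift or slippage, gravity
artifacts, activity-specific temporal structure (cyclic vs discrete
movements), and the start/end detection problem (windows are known by
construction). Passing tests on synthetic data therefore demonstrate that
the estimator machinery is correct and self-consistent — not that the
published accuracy generalizes; reproducing the published whole-sample
cutoffs and accuracy would require the original raw recordings, which are
not redistributable here. For datasets in the documented CSV dialects the
full pipeline (`extract → learn → loocv`) runs end-to-end unchanged.

## Problem sizes and numerical choices

The standard synthetic validation uses 6 subjects × 5 categories ×
5 repetitions (150 repetitions, ≈ 5 min of 100 Hz signal per subject),
mirroring the 6-participant × 14-activity × 5-repetition design of the
original protocol at category granularity. ROC oracle tests use ≥ 100 random
instances of n ≤ 200 scores with deliberate ties. Timestamps are validated
against the declared rate with relative tolerance 1e-6 (detects corrupt
files without forbidding resampled data); recording CSVs are written with
shortest-unique float representation and parsed with round-trip precision so
write→read is bit-identical. Calibration is a per-axis least-squares line
`raw = value/gain + offset` (≥ 2 distinct reference values required) and is
optional at read time, since pipeline files are normally already in physical
units.

## Known limitations

* The criterion-based accuracy and the routing accuracy disagree exactly on
  mis-branched repetitions; both are reported, but summary tables use the
  criterion view.
* `fwr_active` assumes the most active hand is the functionally active one;
  pathologies with a hyperkinetic "stabilizing" hand would violate this.
* The midpoint threshold convention reproduces published cutoff values only
  up to the (unknown) convention of the original analysis.
* Five categories, not 14 activities: per-activity recognition, onset/offset
  detection and ML extensions are out of scope.
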