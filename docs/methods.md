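# Methods

This note documents the models, conventions and numerical choices behind
`ctgrisk`, and what its synthetic cohorts do and do not establish about real
cardiotocography data.

## Feature extraction

**Baseline.** The baseline is an iterative trimmed moving average: a
10-minute windowed mean recomputed after excluding samples deviating more
than 10 bpm from the current estimate, iterated to convergence (tolerance
0.1 bpm, at most 20 iterations), initialised at the global median. Windows
are truncated (zero-padded normalised convolution) at the trace edges. This
realises "the average FHR excluding any major deviations" while keeping the
estimate within 2 bpm of truth under a planted 60-s, 30-bpm deceleration and
within 3 bpm of a 130→150 bpm linear drift.

**Events.** Accelerations are maximal runs of deviation ≥ +10 bpm lasting
more than 15 s; decelerations are maximal runs ≤ −10 bpm that sustain
≥ 20 bpm for more than 30 s or last more than 60 s. Duration thresholds are
strict and use the half-open sample convention (offset = last sample time +
one sample period). Runs separated by less than 5 s of sub-threshold or
missing samples are bridged, so sampling noise cannot split one
physiological event. Lost beats integrate the depth below baseline over the
event (Σ depth·dt, in beats); for a rectangular deceleration this equals the
duration × magnitude product, and it remains well defined for non-rectangular
morphology.

**STV.** FHR is converted to pulse intervals (60000/FHR, ms) and averaged on
3.75-s epochs (16 per minute, the convention of computerised CTG systems —
the one-line "mean absolute difference between successive pulses" is
otherwise sampling-rate dependent). STV is the mean |Δ| over successive
valid epochs. Epochs are invalid when more than half their samples are
missing, when their minute has more than half its samples missing, or when
they overlap a detected event. We exclude accelerations as well as
decelerations here: both are transient deviations, not variability, and
including acceleration epochs would let event edges masquerade as
high variability.

**Variation episodes.** Each minute is classified by the range of its valid
epoch pulse intervals: ≥ 32 ms qualifies as high variation, ≤ 30 ms as low
variation (published computerised-CTG conventions; the thresholds are module
constants). Minutes overlapping any detected event, or with fewer than 8
valid epochs, are not classified — a partially event-covered minute would
otherwise be judged on a truncated sample of epochs. An episode requires at
least 5 qualifying minutes within some 6-minute window; qualifying minutes
covered by any such window are counted. A consequence worth noting: any
nonzero per-trace episode time is at least 5 minutes.

**Analysis cap.** All features are computed on the first min(duration, 60)
minutes; basal FHR is the time-average of the baseline over that window and
signal loss is the missing-sample percentage within it.

## Synthetic cohorts

The generator works backwards from target feature values. Per trace it
draws the seven targets from per-cohort quantile-interpolated distributions
(piecewise-linear quantile functions through configured q1/median/q3 plus
tail knots), then renders a signal realising them:

- baseline = basal target plus a small linear drift (± 2 bpm);
- variability is generated on the pulse-interval scale as a bounded zigzag
  walk whose step equals the STV target and whose per-minute band is set by
  the planted regime: high-variation minutes use a band that is an exact
  multiple of the step (so the walk lands on the band walls and the minute
  range is pinned ≥ 33 ms), low-variation minutes a band ≤ 24 ms, and
  neutral minutes a band pinned at 31 ms — between the 30 and 32 ms
  thresholds — so they classify as neither. Small epoch jitter (0.15 ms)
  and sample noise (0.3 ms) are added; both are far smaller than the 1 ms
  guard bands;
- events are trapezoids placed in neutral minutes at least one minute clear
  of episode blocks, with amplitudes and durations exceeding the detection
  thresholds by configurable margins (defaults: +4 bpm, +5 s); variability
  is damped to 30% inside events so the planted amplitude, not the wiggle,
  determines detectability. Deceleration area equals the drawn lost-beats
  target exactly;
- signal loss is planted as whole-minute blackouts in event-free neutral
  minutes (plus at most one partial block beyond the 60-minute analysis
  window), so missingness can never silently erase or create an episode.
  The planted truth records exactly what was placed.

Default targets follow the published group medians/IQRs wherever the
extraction conventions make them jointly feasible, with three deliberate
deviations, all documented here because they are conditions of the study
design rather than tuning knobs:

1. **Most lost beats is targeted conditional on ≥ 1 deceleration.** With
   deceleration medians of 0 in both cohorts, the unconditional MLB median
   is necessarily 0; and any deceleration meeting the printed criteria loses
   ≥ ~13 beats (20 bpm × >30 s, with margins), so conditional medians below
   that floor are unreachable. Defaults: 15 (normal) vs 19 (adverse),
   preserving the published direction and approximate ratio.
2. **Adverse-cohort episode-time medians respect the 5-minute episode
   floor.** Published medians of 2 min (high variation) and 4 min (low
   variation) are unreachable when any nonzero episode time is ≥ 5 min; the
   defaults use 0 and 5 min, preserving both directions. Draws below 2.5 min
   collapse to zero and draws up to 6.5 min are promoted to one minimal
   episode — the quantisation the persistence rule imposes.
3. **Basal-rate tails are slightly separated** (normal 124–146, adverse
   128–148 bpm) so the 1-bpm median difference between groups is backed by
   a ~1.2 bpm mean difference; the printed quartiles are unchanged. Without
   this the direction of a 1-bpm shift against a 12-bpm IQR is a coin flip
   at n = 500 per cohort.

Covariates overlap fully across cohorts (gestational age uniform over
189–258 days, durations 30–75 min), so matching is feasible; fetal sex is
assigned by exact quota (48.8% male), making cohort composition
deterministic. Subtype labels use a Gaussian copula with a shared severity
factor (loading √0.3 by default); every adverse record carries at least one
label (the nearest-to-threshold label is forced when none fires). Note that
conditioning on "at least one label" removes most of the shared-factor
variance from the observable pairwise correlations (a Berkson effect); the
co-occurrence boost is visible instead as a higher mean number of labels per
record.

**What passing tests do and do not show.** The generator's traces are
stylised: variability is a deterministic zigzag with pinned minute ranges,
events are clean trapezoids placed away from episodes, missingness is
block-structured, and the seven features are drawn independently per trace.
Exact planted-truth recovery therefore validates the *extraction logic*, not
its robustness to real transducer noise, fetal movement artefact, or the
correlated feature structure of real pregnancies. Likewise the classifiers'
validation AUC (≈ 0.97 at default separation) exceeds what the same feature
set achieves on real data, where features are correlated and group overlap
is larger; the discrimination test checks the pipeline clears the
"excellent" 0.80 band under known separation, not a clinical claim.

## Cohort construction

QC inequalities are strict exactly as printed; boundary values are retained.
The acceleration-rate rule divides by the analysed (≤ 60 min) duration, the
same window the features come from. Whether the 125-lost-beats rule applies
before or after the cap is unspecified; it is applied after, consistent with
every other rule. The matched analysis set keeps all cases plus their
matched controls (cases outnumber controls in the emulated design, so
sampling is without replacement on the control side; unmatched cases are
kept and reported). Matching is greedy nearest-neighbour on the logit
propensity score, cases in descending propensity, caliper 0.2 × SD of the
logit score. The 80:20 split uses largest-remainder rounding per stratum
(outcome × gestational week × 10-min duration bin × sex) with the global
training size exactly round(0.8 N); singleton strata go to training with a
warning. Feature transforms choose z-score vs min-max by |sample skewness|
vs 1.0, fitted on training data only and never re-estimated; out-of-range
validation values are logged, not clipped.

## Modelling and tuning

Search spaces are finite and declared in `models.DEFAULT_SPACES`
(tree depth 2–20, forest size 100–400, regularisation log-uniform 1e-3–1e3,
etc. — desk-scale ranges chosen for reproducibility on one CPU). The tuner
is a small sequential model-based optimiser: parameters map to the unit
cube, a Matern-5/2 Gaussian process with estimated noise models the mean
fold AUC, and expected improvement over a 256-point random candidate set
picks the next configuration; it is deterministic given seed and budget
(default 50 evaluations per family; the acceptance script uses 6).
Margin-based models (SVM) receive a monotone logistic link fitted on
out-of-fold decision values so Brier scores and decision curves are
meaningful. No multiclass subtype model is built — subtypes co-occur, so
per-subtype evaluation uses a one-vs-all-controls framing instead.

## Evaluation conventions

AUC uses the rank (Mann–Whitney) formulation; agreement with trapezoidal
ROC integration to 1e-12 is asserted in tests. Bootstrap CIs are percentile
intervals over class-stratified resamples (B = 1000 default); degenerate
resamples are redrawn and counted. Operating-point metrics are reported
×100 (thresholds, sensitivity, specificity, F1, and Cohen's κ, matching the
clinical reporting convention); Youden ties break toward the lower threshold
(higher sensitivity — the clinically conservative choice); 95%-sensitivity
takes the highest qualifying threshold and 95%-specificity the lowest, and
an unreachable constraint is flagged, never clamped. Net benefit is
NB(pt) = TP/N − (FP/N)·pt/(1−pt) over thresholds 0.01–0.99 (pt = 1 is
excluded — division by zero); treat-all equals prevalence − (1−prevalence)
·pt/(1−pt) and crosses zero at the prevalence. Feature associations use
two-sided Mann–Whitney tests (α = 0.05) with Cohen's D for approximately
symmetric features and rank-biserial correlation (2·AUC − 1) otherwise —
the same symmetry rule as the transforms.

## Determinism and problem sizes

A single run seed fans out to per-stage 31-bit seeds via SHA-256 of
"seed:stage"; reports regenerate bit-identically. The shipped tests and the
acceptance script run the generator at n = 500–1000 per cohort and tuning
budgets of 6–8 evaluations — sizes chosen so the full study design executes
on a single CPU in minutes while keeping every statistical check
well-powered; all are configuration parameters, and larger runs only
require changing them.

## Known limitations

- The generator plants features independently per trace; real FHR features
  are correlated (low STV accompanies low-variation episodes), so synthetic
  discrimination overstates real-world discrimination.
- Episode thresholds and the STV epoching are fixed conventions; vendor
  systems differ in detail.
- The baseline estimator assumes deviations are transient relative to the
  10-minute window; sustained baseline shifts (e.g. prolonged bradycardia)
  would be partially absorbed.
- No toco (uterine activity) or fetal-movement channel is modelled or used.
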